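import numpy as np
import pandas as pd
import pytest

from grstrial.outcome_stats import (
    AnalysisError,
    analyze_outcomes,
    apply_carry_forward,
    hodges_lehmann_shift,
    subgroup_analysis,
)
from grstrial.snp_score import ReferenceDistribution
from grstrial.synthetic_data import TrialSimConfig, simulate_trial
from grstrial.trial_design import VisitRecord, assemble_ledger, permuted_block_randomize


def brute_force_hl(x, y):
    """Independent all-pairs oracle: explicit loop, manual midpoint median."""
    diffs = sorted(xi - yj for xi in x for yj in y)
    k = len(diffs)
    if k % 2 == 1:
        return diffs[k // 2]
    return 0.5 * (diffs[k // 2 - 1] + diffs[k // 2])


def build_ledger(visit_values, arms=None, extra=None):
    """visit_values: {pid: {visit: {column: value}}}; absent visit = unattended."""
    pids = list(visit_values)
    if arms is None:
        arms = ["GRS" if i % 2 == 0 else "SOC" for i in range(len(pids))]
    assignments = pd.DataFrame(
        {"participant_id": pids, "arm": arms,
         "sequence_index": range(len(pids)), "block_index": 0}
    )
    records = []
    for pid, visits in visit_values.items():
        for visit in (1, 2, 3):
            if visit in visits:
                records.append(VisitRecord(participant_id=pid, visit=visit,
                                           attended=True, **visits[visit]))
    return assemble_ledger(assignments, records, participant_extra=extra)


class TestCarryForward:
    def test_lipid_baseline_fills_missing_3mo(self):
        ledger = build_ledger({
            "A": {1: {"ldl": 150.0}, 2: {}, 3: {"ldl": 130.0}},
            "B": {1: {"ldl": 140.0}, 2: {"ldl": 138.0}, 3: {"ldl": 120.0}},
        })
        ds = apply_carry_forward(ledger, "ldl", mode="imputation")
        row = ds.data.set_index("participant_id").loc["A"]
        assert row["included"]
        assert row["value_3mo"] == 150.0
        assert row["prov_3mo"] == "carried_forward"
        assert row["delta"] == pytest.approx(-20.0)

    def test_no_imputation_mode_excludes_same_participant(self):
        ledger = build_ledger({
            "A": {1: {"ldl": 150.0}, 2: {}, 3: {"ldl": 130.0}},
        })
        ds = apply_carry_forward(ledger, "ldl", mode="no_imputation")
        row = ds.data.iloc[0]
        assert not row["included"]
        assert "no-imputation" in row["exclusion_reason"]

    def test_missing_final_lipid_excludes(self):
        ledger = build_ledger({"A": {1: {"ldl": 150.0}, 2: {"ldl": 140.0}}})
        ds = apply_carry_forward(ledger, "ldl")
        assert not ds.data.iloc[0]["included"]
        assert "final" in ds.data.iloc[0]["exclusion_reason"]

    def test_questionnaire_missing_at_final_and_earlier_excludes(self):
        ledger = build_ledger({"A": {1: {"diet_score": 3.0}, 2: {}, 3: {}}})
        ds = apply_carry_forward(ledger, "diet_score")
        row = ds.data.iloc[0]
        assert not row["included"]
        assert "final visit and an earlier visit" in row["exclusion_reason"]

    def test_questionnaire_carries_forward_both_directions(self):
        ledger = build_ledger({
            # missing at visit 2 only -> baseline carried to 3mo
            "A": {1: {"diet_score": 3.0}, 2: {}, 3: {"diet_score": 4.0}},
            # missing at visit 3 only -> 3mo value carried to 6mo, delta 0
            "B": {1: {"diet_score": 2.0}, 2: {"diet_score": 2.5}, 3: {}},
        })
        ds = apply_carry_forward(ledger, "diet_score")
        frame = ds.data.set_index("participant_id")
        assert frame.loc["A", "value_3mo"] == 3.0
        assert frame.loc["A", "prov_3mo"] == "carried_forward"
        assert frame.loc["A", "delta"] == pytest.approx(1.0)
        assert frame.loc["B", "value_6mo"] == 2.5
        assert frame.loc["B", "prov_6mo"] == "carried_forward"
        assert frame.loc["B", "delta"] == pytest.approx(0.0)

    def test_measurement_requires_both_visits(self):
        ledger = build_ledger({
            "A": {1: {"weight": 80.0}, 2: {"weight": 81.0}},
            "B": {1: {"weight": 90.0}, 2: {"weight": 91.0}, 3: {"weight": 89.0}},
        })
        ds = apply_carry_forward(ledger, "weight")
        frame = ds.data.set_index("participant_id")
        assert not frame.loc["A", "included"]
        assert frame.loc["B", "included"]

    def test_never_fabricates_from_nothing(self):
        ledger = build_ledger({"A": {1: {}, 2: {}, 3: {}}})
        for outcome in ("ldl", "weight", "diet_score"):
            ds = apply_carry_forward(ledger, outcome)
            row = ds.data.iloc[0]
            assert not row["included"]
            assert np.isnan(row["value_3mo"]) and np.isnan(row["value_6mo"])

    def test_provenance_partitions_included_values(self, default_trial):
        for outcome in ("ldl", "diet_score", "weight"):
            ds = apply_carry_forward(default_trial.ledger, outcome)
            included = ds.included()
            assert included["prov_3mo"].isin(["observed", "carried_forward"]).all()
            assert included["prov_6mo"].isin(["observed", "carried_forward"]).all()
            excluded = ds.data[~ds.data["included"]]
            assert (excluded["exclusion_reason"] != "").all()

    def test_unknown_outcome_errors(self, default_trial):
        with pytest.raises(AnalysisError, match="unknown outcome"):
            apply_carry_forward(default_trial.ledger, "shoe_size")


class TestHodgesLehmann:
    def test_forced_four_pair_example(self):
        est = hodges_lehmann_shift(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        # pairwise diffs {1, 0, 2, 1} -> median 1
        assert est.hl_difference == pytest.approx(1.0)

    def test_identical_samples(self, rng):
        x = rng.normal(size=12)
        est = hodges_lehmann_shift(x, x.copy())
        assert est.hl_difference == pytest.approx(0.0)
        assert est.p_value > 0.9

    def test_translation_equivariance(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=11)
        base = hodges_lehmann_shift(x, y)
        shifted = hodges_lehmann_shift(x + 2.5, y)
        assert shifted.hl_difference == pytest.approx(base.hl_difference + 2.5)
        assert shifted.ci_low == pytest.approx(base.ci_low + 2.5)
        both = hodges_lehmann_shift(x + 2.5, y + 2.5)
        assert both.p_value == pytest.approx(base.p_value)

    def test_antisymmetry(self, rng):
        x = np.round(rng.normal(size=10), 1)  # rounded -> ties likely
        y = np.round(rng.normal(0.4, 1.0, size=13), 1)
        fwd = hodges_lehmann_shift(x, y)
        rev = hodges_lehmann_shift(y, x)
        assert rev.hl_difference == pytest.approx(-fwd.hl_difference)
        assert rev.ci_low == pytest.approx(-fwd.ci_high)
        assert rev.ci_high == pytest.approx(-fwd.ci_low)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_matches_brute_force_including_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            m, n = rng.integers(2, 31, size=2)
            x = rng.integers(-4, 5, size=m).astype(float)
            y = rng.integers(-4, 5, size=n).astype(float)
            est = hodges_lehmann_shift(x, y)
            assert est.hl_difference == pytest.approx(brute_force_hl(x, y), abs=1e-12)
            assert est.ci_low <= est.hl_difference <= est.ci_high

    def test_ci_coverage_known_shift(self):
        rng = np.random.default_rng(17)
        true_shift = 0.7
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(true_shift, 1.0, size=12)
            y = rng.normal(0.0, 1.0, size=14)
            est = hodges_lehmann_shift(x, y)
            hits += est.ci_low <= true_shift <= est.ci_high
        assert 0.91 <= hits / n_rep <= 0.99

    def test_power_sanity_for_ldl_scale_effect(self):
        rng = np.random.default_rng(23)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(-20.0, 28.0, size=30)
            y = rng.normal(0.0, 28.0, size=35)
            rejections += hodges_lehmann_shift(x, y).p_value < 0.05
        assert rejections / n_rep > 0.5

    def test_tiny_arm_rejected(self):
        with pytest.raises(AnalysisError, match=">=2"):
            hodges_lehmann_shift(np.array([1.0]), np.array([1.0, 2.0]))

    def test_large_samples_use_normal_ci(self, rng):
        x = rng.normal(0.5, 1.0, 150)
        y = rng.normal(0.0, 1.0, 150)
        est = hodges_lehmann_shift(x, y)
        assert est.ci_method == "normal"
        assert est.ci_low <= est.hl_difference <= est.ci_high
        assert est.ci_low <= 0.5 <= est.ci_high  # sanity at this effect/sample size


class TestAnalyzeOutcomes:
    def test_constructed_separation_recovered_exactly(self):
        values = {}
        arms = []
        for i in range(12):
            pid = f"P{i:02d}"
            arm = "GRS" if i < 6 else "SOC"
            arms.append(arm)
            drop = 20.0 if arm == "GRS" else 0.0
            base = 140.0 + i  # distinct values avoid degenerate ties
            values[pid] = {
                1: {"ldl": base},
                2: {"ldl": base},
                3: {"ldl": base - drop},
            }
        ledger = build_ledger(values, arms=arms)
        report = analyze_outcomes(ledger, outcome_rows=[("ldl", "imputation")],
                                  include_medications=False)
        (row,) = report.rows
        assert row.estimate.hl_difference == pytest.approx(-20.0)

    def test_default_report_shape(self, default_trial):
        report = analyze_outcomes(default_trial.ledger)
        kinds = [r.kind for r in report.rows]
        assert kinds.count("outcome") == 9
        assert kinds.count("sensitivity") == 1
        assert kinds.count("medication") == 4
        assert len(report.rows) == 14
        assert report.comparison_count <= 14

    def test_imputation_and_no_imputation_have_distinct_n(self, default_trial):
        report = analyze_outcomes(default_trial.ledger)
        by_mode = {r.mode: r for r in report.rows if r.outcome == "ldl"}
        n_imp = by_mode["imputation"].estimate.n_grs + by_mode["imputation"].estimate.n_soc
        n_no = by_mode["no_imputation"].estimate.n_grs + by_mode["no_imputation"].estimate.n_soc
        assert n_imp >= n_no

    def test_failed_outcome_contained(self):
        # diet data entirely absent -> diet row errors, ldl row survives
        values = {
            f"P{i}": {1: {"ldl": 140.0 + i}, 2: {"ldl": 139.0 + i}, 3: {"ldl": 130.0 + i}}
            for i in range(8)
        }
        ledger = build_ledger(values)
        report = analyze_outcomes(
            ledger,
            outcome_rows=[("ldl", "imputation"), ("diet_score", "imputation")],
            include_medications=False,
        )
        by_outcome = {r.outcome: r for r in report.rows}
        assert by_outcome["ldl"].error is None
        assert by_outcome["diet_score"].error is not None

    def test_medication_rows_report_proportions(self, default_trial):
        report = analyze_outcomes(default_trial.ledger)
        med = [r for r in report.rows if r.kind == "medication"]
        for row in med:
            assert row.visit in (2, 3)
            if row.error is None:
                assert 0.0 <= row.prop_grs <= 1.0
                assert 0.0 <= row.p_value <= 1.0


class TestSubgroups:
    def test_high_grs_keeps_full_soc_arm(self, default_trial):
        full = analyze_outcomes(default_trial.ledger,
                                outcome_rows=[("ldl", "imputation")],
                                include_medications=False)
        sub = subgroup_analysis(default_trial.ledger, "high_grs",
                                outcome_rows=[("ldl", "imputation")])
        assert sub.rows[0].estimate.n_soc == full.rows[0].estimate.n_soc
        assert sub.rows[0].estimate.n_grs < full.rows[0].estimate.n_grs

    def test_empty_high_grs_subgroup_errors(self, default_trial):
        ledger = default_trial.ledger
        lowered = ledger.participants.copy()
        lowered.loc[lowered["arm"] == "GRS", "grs_percentile"] = 0.3
        from grstrial.trial_design import TrialLedger

        with pytest.raises(AnalysisError, match="empty"):
            subgroup_analysis(TrialLedger(lowered, ledger.visits), "high_grs")

    def test_degenerate_attitude_split_flagged(self):
        values = {
            f"P{i}": {1: {"med_beliefs_likert": 18.0, "ldl": 140.0},
                      2: {"ldl": 139.0}, 3: {"ldl": 130.0}}
            for i in range(8)
        }
        ledger = build_ledger(values)
        with pytest.raises(AnalysisError, match="degenerate"):
            subgroup_analysis(ledger, "positive_med_attitude")

    def test_unknown_subgroup_errors(self, default_trial):
        with pytest.raises(AnalysisError, match="unknown subgroup"):
            subgroup_analysis(default_trial.ledger, "left_handed")

    def test_interaction_effect_concentrates_in_subgroup(self, reference):
        config = TrialSimConfig(high_grs_interaction={"weight": -3.0})
        sub_means, full_means = [], []
        for seed in range(10):
            trial = simulate_trial(config, ref=reference, seed=seed)
            sub = subgroup_analysis(trial.ledger, "high_grs",
                                    outcome_rows=[("weight", "imputation")])
            full = analyze_outcomes(trial.ledger,
                                    outcome_rows=[("weight", "imputation")],
                                    include_medications=False)
            if sub.rows[0].error is None and full.rows[0].error is None:
                sub_means.append(sub.rows[0].estimate.hl_difference)
                full_means.append(full.rows[0].estimate.hl_difference)
        assert len(sub_means) >= 8
        # subgroup recovers close to the injected -3; the full analysis is
        # diluted by the unaffected below-median participants
        assert np.mean(sub_means) < -1.8
        assert np.mean(full_means) > np.mean(sub_means) + 1.0

    def test_null_trial_type_one_error_small_sample(self, reference):
        # light version of the calibration check: one outcome, 120 trials
        rejections = 0
        analyzed = 0
        for seed in range(120):
            trial = simulate_trial(TrialSimConfig(), ref=reference, seed=seed)
            report = analyze_outcomes(trial.ledger,
                                      outcome_rows=[("weight", "imputation")],
                                      include_medications=False)
            if report.rows[0].error is None:
                analyzed += 1
                rejections += report.rows[0].estimate.p_value < 0.05
        assert analyzed >= 110
        assert 0.01 <= rejections / analyzed <= 0.10
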