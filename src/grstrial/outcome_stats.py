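"""Arm-difference analysis: carry-forward datasets and Hodges-Lehmann shifts.

The analysis dataset for each outcome applies the study's missing-data rules
(baseline carry-forward for questionnaires and lipids, exclusion when too
little is observed), then the between-arm difference of 3-to-6-month changes
is estimated by the Hodges-Lehmann shift (median of all pairwise differences)
with a confidence interval from inverting the Wilcoxon-Mann-Whitney rank-sum
distribution — exactly when the pair count is small enough, by normal
approximation with tie correction otherwise.  Medication use is compared as
proportions with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, norm

from .trial_design import TrialLedger

__all__ = [
    "OutcomeSpec",
    "OUTCOMES",
    "DEFAULT_REPORT_ROWS",
    "AnalysisDataset",
    "ArmSummary",
    "ShiftEstimate",
    "ReportRow",
    "OutcomeReport",
    "AnalysisError",
    "apply_carry_forward",
    "hodges_lehmann_shift",
    "analyze_outcomes",
    "subgroup_analysis",
]


class AnalysisError(ValueError):
    """Raised when an outcome or subgroup cannot be analyzed."""


@dataclass(frozen=True)
class OutcomeSpec:
    """How one outcome column behaves under the missing-data rules.

    kind 'lipid': baseline value fills a missing 3-month value (unless the
    no-imputation mode is requested); a missing final-visit value excludes the
    participant.  kind 'questionnaire': any missing later value is filled from
    the most recent prior visit; entirely missing at the final visit plus at
    an earlier visit excludes the participant.  kind 'measurement': both
    post-baseline values must be observed.
    """

    name: str
    kind: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("lipid", "measurement", "questionnaire"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")


OUTCOMES: dict[str, OutcomeSpec] = {
    spec.name: spec
    for spec in [
        OutcomeSpec("ldl", "lipid", "LDL-C (mg/dl)"),
        OutcomeSpec("hdl", "lipid", "HDL-C (mg/dl)"),
        OutcomeSpec("total_chol", "lipid", "Total cholesterol (mg/dl)"),
        OutcomeSpec("triglycerides", "lipid", "Triglycerides (mg/dl)"),
        OutcomeSpec("systolic_bp", "measurement", "Systolic BP (mmHg)"),
        OutcomeSpec("diastolic_bp", "measurement", "Diastolic BP (mmHg)"),
        OutcomeSpec("weight", "measurement", "Weight (kg)"),
        OutcomeSpec("diet_score", "questionnaire", "Diet score (0-5)"),
        OutcomeSpec("activity_category", "questionnaire", "Physical activity (1-6)"),
        OutcomeSpec("anxiety_score", "questionnaire", "Anxiety over testing"),
        OutcomeSpec("stages_of_change", "questionnaire", "Stages of change"),
        OutcomeSpec("med_beliefs_likert", "questionnaire", "Beliefs about medicines (aggregate)"),
    ]
}

# Default report shape: nine outcome rows, one lipid sensitivity row, and
# four medication-proportion comparisons appended by analyze_outcomes.
DEFAULT_REPORT_ROWS: list[tuple[str, str]] = [
    ("ldl", "imputation"),
    ("ldl", "no_imputation"),
    ("hdl", "imputation"),
    ("systolic_bp", "imputation"),
    ("diastolic_bp", "imputation"),
    ("weight", "imputation"),
    ("diet_score", "imputation"),
    ("activity_category", "imputation"),
    ("anxiety_score", "imputation"),
    ("stages_of_change", "imputation"),
]

MEDICATION_COMPARISONS: list[tuple[str, int]] = [
    ("on_statin", 2),
    ("on_statin", 3),
    ("on_antihypertensive", 2),
    ("on_antihypertensive", 3),
]


@dataclass
class AnalysisDataset:
    """Per-participant values for one outcome after the missing-data rules.

    ``data`` columns: participant_id, arm, value_3mo, value_6mo, prov_3mo,
    prov_6mo ('observed'/'carried_forward'), delta (6mo - 3mo), included,
    exclusion_reason.
    """

    outcome: str
    mode: str
    data: pd.DataFrame

    def included(self) -> pd.DataFrame:
        return self.data[self.data["included"]]

    def arm_deltas(self, arm: str) -> np.ndarray:
        rows = self.included()
        return rows.loc[rows["arm"] == arm, "delta"].to_numpy(dtype=float)


@dataclass(frozen=True)
class ArmSummary:
    n: int
    mean_3mo: float
    sd_3mo: float
    mean_6mo: float
    sd_6mo: float
    mean_delta: float
    sd_delta: float


@dataclass(frozen=True)
class ShiftEstimate:
    """Hodges-Lehmann location shift (first arm minus second) with 95% CI."""

    n_grs: int
    n_soc: int
    hl_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    ci_method: str = "exact"
    p_method: str = "exact"
    grs: ArmSummary | None = None
    soc: ArmSummary | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.hl_difference <= self.ci_high:
            raise ValueError("CI does not bracket the HL estimate")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _values(frame: pd.DataFrame, column: str, visit: int) -> pd.Series:
    """Observed value per participant at a visit; NaN when unattended/missing."""
    rows = frame[frame["visit"] == visit].set_index("participant_id")
    vals = pd.to_numeric(rows[column], errors="coerce")
    return vals.where(rows["attended"].astype(bool))


def apply_carry_forward(
    ledger: TrialLedger, outcome: str, mode: str = "imputation"
) -> AnalysisDataset:
    """Build the analysis dataset for one outcome under the carry-forward rules."""
    spec = OUTCOMES.get(outcome)
    if spec is None:
        raise AnalysisError(f"unknown outcome {outcome!r}; known: {sorted(OUTCOMES)}")
    if mode not in ("imputation", "no_imputation"):
        raise AnalysisError(f"unknown mode {mode!r}")

    arm = ledger.arm_of()
    v1 = _values(ledger.visits, outcome, 1)
    v2 = _values(ledger.visits, outcome, 2)
    v3 = _values(ledger.visits, outcome, 3)

    rows = []
    for pid in ledger.participants["participant_id"]:
        a, b, c = v1.get(pid), v2.get(pid), v3.get(pid)
        has1, has2, has3 = pd.notna(a), pd.notna(b), pd.notna(c)
        val2 = val3 = np.nan
        prov2 = prov3 = ""
        reason = ""

        if spec.kind == "questionnaire":
            if not has3 and not (has1 and has2):
                reason = "questionnaire missing at final visit and an earlier visit"
            else:
                if has2:
                    val2, prov2 = b, "observed"
                elif has1:
                    val2, prov2 = a, "carried_forward"
                else:
                    reason = "no 3-month or prior response to carry forward"
                if not reason:
                    if has3:
                        val3, prov3 = c, "observed"
                    else:
                        val3, prov3 = val2, "carried_forward"
        elif spec.kind == "lipid":
            if not has3:
                reason = "no lipid panel after final visit"
            elif has2:
                val2, prov2 = b, "observed"
                val3, prov3 = c, "observed"
            elif mode == "imputation" and has1:
                val2, prov2 = a, "carried_forward"
                val3, prov3 = c, "observed"
            elif mode == "imputation":
                reason = "no 3-month or baseline lipid value"
            else:
                reason = "no observed 3-month lipid value (no-imputation mode)"
        else:  # measurement
            if has2 and has3:
                val2, prov2 = b, "observed"
                val3, prov3 = c, "observed"
            else:
                reason = "measurement not observed at both post-baseline visits"

        included = reason == ""
        rows.append(
            {
                "participant_id": pid,
                "arm": arm[pid],
                "value_3mo": float(val2) if included else np.nan,
                "value_6mo": float(val3) if included else np.nan,
                "prov_3mo": prov2,
                "prov_6mo": prov3,
                "delta": float(val3) - float(val2) if included else np.nan,
                "included": included,
                "exclusion_reason": reason,
            }
        )
    return AnalysisDataset(outcome=outcome, mode=mode, data=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Hodges-Lehmann shift with rank-sum-inversion CI


@lru_cache(maxsize=512)
def _u_cdf(m: int, n: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic for sample sizes m, n.

    Counts come from the Gaussian binomial recurrence
    G(i, j) = q^j G(i-1, j) + G(i, j-1); float64 counts are exact to ~1e-16
    relative error, ample for quantile lookup.
    """
    if m > n:
        m, n = n, m
    row = [np.ones(1) for _ in range(m + 1)]  # G(i, 0)
    for j in range(1, n + 1):
        new_row = [np.ones(1)]
        for i in range(1, m + 1):
            arr = np.zeros(i * j + 1)
            prev = new_row[i - 1]  # G(i-1, j)
            arr[j : j + prev.size] += prev
            side = row[i]  # G(i, j-1)
            arr[: side.size] += side
            new_row.append(arr)
        row = new_row
    counts = row[m]
    return np.cumsum(counts) / counts.sum()


def _tie_corrected_sigma(m: int, n: int, combined: np.ndarray) -> float:
    N = m + n
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    return math.sqrt(max(var, 0.0))


def hodges_lehmann_shift(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    exact_ci_limit: int = 10_000,
) -> ShiftEstimate:
    """Estimate the location shift of ``x`` relative to ``y``.

    The estimate is the median of all pairwise differences x_i - y_j (midpoint
    of the two central values when their count is even).  The CI inverts the
    rank-sum null distribution: exactly when ``m * n <= exact_ci_limit``, else
    by normal approximation with tie correction.  The p-value is the two-sided
    Wilcoxon-Mann-Whitney test (exact when tie-free and small, midrank
    asymptotics with continuity correction otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise AnalysisError(f"need >=2 values per arm, got {m} and {n}")

    diffs = np.sort(np.subtract.outer(x, y).ravel())
    mn = m * n
    hl = float(np.median(diffs))

    if mn <= exact_ci_limit:
        cdf = _u_cdf(m, n)
        # smallest q with P(U <= q) >= alpha/2, floored at 1 (R convention)
        qu = int(np.searchsorted(cdf, alpha / 2.0, side="left"))
        qu = max(qu, 1)
        ci_low, ci_high = float(diffs[qu - 1]), float(diffs[mn - qu])
        ci_method = "exact"
    else:
        sigma = _tie_corrected_sigma(m, n, np.concatenate([x, y]))
        k = int(mn / 2.0 - norm.ppf(1 - alpha / 2.0) * sigma)
        k = min(max(k, 0), mn // 2 - 1) if mn >= 2 else 0
        ci_low, ci_high = float(diffs[k]), float(diffs[mn - 1 - k])
        ci_method = "normal"

    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and mn <= 2_500:
        p = float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        p_method = "exact"
    else:
        if _tie_corrected_sigma(m, n, combined) == 0.0:
            p = 1.0  # all observations identical
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
        p_method = "asymptotic"

    return ShiftEstimate(
        n_grs=m,
        n_soc=n,
        hl_difference=hl,
        ci_low=min(ci_low, hl),
        ci_high=max(ci_high, hl),
        p_value=min(p, 1.0),
        ci_method=ci_method,
        p_method=p_method,
    )


def _arm_summary(frame: pd.DataFrame) -> ArmSummary:
    def ms(col: str) -> tuple[float, float]:
        vals = frame[col].to_numpy(dtype=float)
        return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    m3, s3 = ms("value_3mo")
    m6, s6 = ms("value_6mo")
    md, sd = ms("delta")
    return ArmSummary(len(frame), m3, s3, m6, s6, md, sd)


def _shift_for_dataset(dataset: AnalysisDataset, alpha: float) -> ShiftEstimate:
    included = dataset.included()
    grs = included[included["arm"] == "GRS"]
    soc = included[included["arm"] == "SOC"]
    if grs.empty or soc.empty:
        raise AnalysisError(
            f"outcome {dataset.outcome!r}: an arm is empty after exclusions "
            f"(GRS n={len(grs)}, SOC n={len(soc)})"
        )
    estimate = hodges_lehmann_shift(
        grs["delta"].to_numpy(float), soc["delta"].to_numpy(float), alpha=alpha
    )
    return replace(estimate, grs=_arm_summary(grs), soc=_arm_summary(soc))


@dataclass
class ReportRow:
    kind: str  # outcome | sensitivity | medication
    outcome: str
    label: str
    mode: str = "imputation"
    estimate: ShiftEstimate | None = None
    visit: int | None = None
    n_grs: int | None = None
    n_soc: int | None = None
    prop_grs: float | None = None
    prop_soc: float | None = None
    p_value: float | None = None
    error: str | None = None


@dataclass
class OutcomeReport:
    rows: list[ReportRow]
    subgroup: str | None = None

    @property
    def comparison_count(self) -> int:
        return sum(1 for r in self.rows if r.error is None)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec: dict = {
                "kind": r.kind,
                "outcome": r.outcome,
                "label": r.label,
                "mode": r.mode,
                "visit": r.visit,
                "error": r.error,
            }
            if r.estimate is not None:
                e = r.estimate
                rec.update(
                    n_grs=e.n_grs,
                    n_soc=e.n_soc,
                    hl_difference=e.hl_difference,
                    ci_low=e.ci_low,
                    ci_high=e.ci_high,
                    p_value=e.p_value,
                )
                for arm_name, summ in (("grs", e.grs), ("soc", e.soc)):
                    if summ is not None:
                        rec.update(
                            {
                                f"{arm_name}_mean_3mo": summ.mean_3mo,
                                f"{arm_name}_sd_3mo": summ.sd_3mo,
                                f"{arm_name}_mean_6mo": summ.mean_6mo,
                                f"{arm_name}_sd_6mo": summ.sd_6mo,
                                f"{arm_name}_mean_delta": summ.mean_delta,
                                f"{arm_name}_sd_delta": summ.sd_delta,
                            }
                        )
            else:
                rec.update(
                    n_grs=r.n_grs,
                    n_soc=r.n_soc,
                    prop_grs=r.prop_grs,
                    prop_soc=r.prop_soc,
                    p_value=r.p_value,
                )
            records.append(rec)
        return pd.DataFrame(records)


def _medication_row(ledger: TrialLedger, column: str, visit: int) -> ReportRow:
    arm = ledger.arm_of()
    frame = ledger.visits
    rows = frame[(frame["visit"] == visit) & frame["attended"].astype(bool)]
    rows = rows[rows[column].notna()]
    label = f"{column.removeprefix('on_')} use at visit {visit}"
    if rows.empty:
        return ReportRow(
            kind="medication", outcome=column, label=label, visit=visit,
            error="no observed medication data",
        )
    flags = rows.set_index("participant_id")[column].astype(bool)
    arms = arm.loc[flags.index]
    table = np.zeros((2, 2), dtype=int)
    for i, a in enumerate(("GRS", "SOC")):
        sel = flags[arms == a]
        table[i] = [int(sel.sum()), int((~sel).sum())]
    n_grs, n_soc = int(table[0].sum()), int(table[1].sum())
    if n_grs == 0 or n_soc == 0:
        return ReportRow(
            kind="medication", outcome=column, label=label, visit=visit,
            error="an arm has no observed medication data",
        )
    _, p = fisher_exact(table, alternative="two-sided")
    return ReportRow(
        kind="medication",
        outcome=column,
        label=label,
        visit=visit,
        n_grs=n_grs,
        n_soc=n_soc,
        prop_grs=table[0, 0] / n_grs,
        prop_soc=table[1, 0] / n_soc,
        p_value=float(p),
    )


def analyze_outcomes(
    ledger: TrialLedger,
    outcome_rows: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    include_medications: bool = True,
) -> OutcomeReport:
    """Produce the full per-outcome report: Hodges-Lehmann rows for every
    configured (outcome, mode) pair plus medication-proportion comparisons.

    A failure in one outcome is contained in its row's ``error`` field.
    """
    rows: list[ReportRow] = []
    seen_outcomes: set[str] = set()
    for outcome, mode in outcome_rows or DEFAULT_REPORT_ROWS:
        spec = OUTCOMES.get(outcome)
        if spec is None:
            raise AnalysisError(f"unknown outcome {outcome!r} in report config")
        kind = "sensitivity" if outcome in seen_outcomes or mode == "no_imputation" else "outcome"
        seen_outcomes.add(outcome)
        label = spec.label + (", no imputation" if mode == "no_imputation" else "")
        try:
            dataset = apply_carry_forward(ledger, outcome, mode)
            estimate = _shift_for_dataset(dataset, alpha)
            rows.append(ReportRow(kind=kind, outcome=outcome, label=label, mode=mode, estimate=estimate))
        except AnalysisError as exc:
            rows.append(ReportRow(kind=kind, outcome=outcome, label=label, mode=mode, error=str(exc)))
    if include_medications:
        for column, visit in MEDICATION_COMPARISONS:
            rows.append(_medication_row(ledger, column, visit))
    return OutcomeReport(rows=rows)


SUBGROUP_OUTCOMES: dict[str, list[tuple[str, str]]] = {
    "high_grs": [("ldl", "imputation"), ("weight", "imputation"), ("activity_category", "imputation")],
    "positive_med_attitude": [("ldl", "imputation")],
}


def _restrict_ledger(ledger: TrialLedger, keep_ids: set[str]) -> TrialLedger:
    participants = ledger.participants[
        ledger.participants["participant_id"].isin(keep_ids)
    ].reset_index(drop=True)
    visits = ledger.visits[ledger.visits["participant_id"].isin(keep_ids)].reset_index(drop=True)
    return TrialLedger(participants=participants, visits=visits)


def subgroup_analysis(
    ledger: TrialLedger,
    subgroup: str,
    outcome_rows: list[tuple[str, str]] | None = None,
    percentile_threshold: float = 0.5,
    alpha: float = 0.05,
) -> OutcomeReport:
    """Run the two pre-specified subgroup analyses.

    ``high_grs`` keeps GRS-arm participants whose reference percentile exceeds
    the threshold and compares them against the FULL standard-of-care arm.
    ``positive_med_attitude`` keeps, in BOTH arms, participants whose baseline
    beliefs-about-medicines aggregate exceeds the within-study median.
    """
    participants = ledger.participants
    if subgroup == "high_grs":
        if "grs_percentile" not in participants.columns:
            raise AnalysisError("ledger participants need a grs_percentile column")
        grs_mask = (participants["arm"] == "GRS") & (
            participants["grs_percentile"] > percentile_threshold
        )
        if not grs_mask.any():
            raise AnalysisError("high_grs subgroup is empty (no GRS-arm percentile above threshold)")
        keep = set(participants.loc[grs_mask, "participant_id"]) | set(
            participants.loc[participants["arm"] == "SOC", "participant_id"]
        )
    elif subgroup == "positive_med_attitude":
        baseline = _values(ledger.visits, "med_beliefs_likert", 1).dropna()
        if baseline.empty:
            raise AnalysisError("no baseline beliefs-about-medicines aggregates available")
        cutoff = float(baseline.median())
        above = baseline[baseline > cutoff]
        if above.empty:
            raise AnalysisError(
                "degenerate attitude split: no aggregate exceeds the within-study median "
                f"({cutoff:g}); scores may be tied"
            )
        keep = set(above.index)
    else:
        raise AnalysisError(f"unknown subgroup {subgroup!r}")

    restricted = _restrict_ledger(ledger, keep)
    report = analyze_outcomes(
        restricted,
        outcome_rows=outcome_rows or SUBGROUP_OUTCOMES[subgroup],
        alpha=alpha,
        include_medications=False,
    )
    report.subgroup = subgroup
    return report
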