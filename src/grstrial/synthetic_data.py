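"""Synthetic reference cohorts and trial datasets.

Everything downstream of genotyping is exercised on data generated here: a
reference cohort with Hardy-Weinberg genotypes and incident events whose log
risk is linear in the standardized score (a configurable truth, default 1.18
per SD), and a two-arm, three-visit trial with configurable arm effects,
retention, and item-level missingness.  All outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import snp_score
from .snp_score import (
    GenotypeMatrix,
    GrsResult,
    ReferenceDistribution,
    SnpWeight,
    fit_reference,
    load_default_weight_table,
    normalize_grs,
)
from .trial_design import (
    Assignment,
    EligibilityInput,
    TrialLedger,
    VisitRecord,
    assemble_ledger,
    check_eligibility,
    permuted_block_randomize,
)

__all__ = [
    "ReferenceSimConfig",
    "TrialSimConfig",
    "ReferenceCohort",
    "TrialData",
    "SimConfigError",
    "draw_allele_freqs",
    "simulate_reference_cohort",
    "simulate_trial",
    "make_fixture_suite",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


# Allele frequencies are population constants of a scenario, not per-draw
# randomness: when a config leaves them unset, every simulator uses the same
# fixed-seed draw so reference and trial cohorts stay mutually consistent.
DEFAULT_FREQ_SEED = 19

def draw_allele_freqs(weights: list[SnpWeight], seed: int = DEFAULT_FREQ_SEED) -> dict[str, float]:
    """Seed-fixed uniform effect-allele frequencies in [0.1, 0.9] per locus."""
    rng = np.random.default_rng(seed)
    return {w.rsid: float(f) for w, f in zip(weights, rng.uniform(0.1, 0.9, len(weights)))}


@dataclass
class ReferenceSimConfig:
    """Reference-cohort generator settings; the default effect-size truth is
    a relative risk of 1.18 per SD of the standardized score."""

    n: int = 8734
    weights: list[SnpWeight] = field(default_factory=load_default_weight_table)
    allele_freqs: dict[str, float] | None = None
    true_rr_per_sd: float = 1.18
    base_event_rate: float = 0.08
    age_range: tuple[float, float] = (45.0, 64.0)
    sex_ratio: float = 0.5  # fraction male
    log_rr_per_year: float = 0.04
    log_rr_male: float = 0.40

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SimConfigError(f"n must be >= 2, got {self.n}")
        if not self.weights:
            raise SimConfigError("weights must be non-empty")
        if not 0.0 < self.base_event_rate < 1.0:
            raise SimConfigError("base_event_rate must be in (0, 1)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise SimConfigError("sex_ratio must be in [0, 1]")
        if self.true_rr_per_sd <= 0:
            raise SimConfigError("true_rr_per_sd must be positive")
        if self.allele_freqs is not None:
            for rsid, f in self.allele_freqs.items():
                if not 0.0 < f < 1.0:
                    raise SimConfigError(f"allele frequency for {rsid} must be in (0, 1)")


@dataclass
class ReferenceCohort:
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame  # sample_id, age, sex
    events: np.ndarray
    grs: list[GrsResult]  # normalized against this cohort's own distribution
    reference: ReferenceDistribution
    allele_freqs: dict[str, float]

    def rr_frame(self) -> pd.DataFrame:
        """Cohort rows shaped for the relative-risk regression."""
        return pd.DataFrame(
            {
                "event": self.events.astype(bool),
                "z": [g.z_score for g in self.grs],
                "age": self.covariates["age"].to_numpy(),
                "sex": self.covariates["sex"].to_numpy(),
            }
        )


def _simulate_genotypes(
    ids: list[str],
    weights: list[SnpWeight],
    allele_freqs: dict[str, float],
    rng: np.random.Generator,
) -> GenotypeMatrix:
    freqs = np.array([allele_freqs[w.rsid] for w in weights])
    dosages = rng.binomial(2, freqs, size=(len(ids), len(weights))).astype(float)
    return GenotypeMatrix(sample_ids=ids, rsids=[w.rsid for w in weights], dosages=dosages)


def simulate_reference_cohort(
    config: ReferenceSimConfig, seed: int = 0
) -> ReferenceCohort:
    """Generate HWE genotypes, age/sex covariates, and incident events.

    The event probability is ``base_event_rate * true_rr_per_sd ** z``
    adjusted additively on the log scale for centered age and male sex; any
    probability above 1 is a config error raised before sampling.
    """
    rng = np.random.default_rng(seed)
    allele_freqs = config.allele_freqs or draw_allele_freqs(config.weights)
    ids = [f"REF{i:05d}" for i in range(config.n)]
    genotypes = _simulate_genotypes(ids, config.weights, allele_freqs, rng)

    raw = snp_score.compute_raw_grs(genotypes, config.weights)
    reference = fit_reference([r.raw_score for r in raw])
    grs = [normalize_grs(r, reference) for r in raw]
    z = np.array([g.z_score for g in grs])

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, config.n)
    male = rng.random(config.n) < config.sex_ratio
    log_p = (
        np.log(config.base_event_rate)
        + np.log(config.true_rr_per_sd) * z
        + config.log_rr_per_year * (age - (lo + hi) / 2.0)
        + config.log_rr_male * male
    )
    p = np.exp(log_p)
    if np.any(p > 1.0):
        raise SimConfigError(
            f"event probability exceeds 1 for {int((p > 1).sum())} draws "
            f"(max {p.max():.3f}); reduce base_event_rate or effect sizes"
        )
    events = rng.random(config.n) < p
    covariates = pd.DataFrame(
        {"sample_id": ids, "age": age, "sex": np.where(male, "male", "female")}
    )
    return ReferenceCohort(
        genotypes=genotypes,
        covariates=covariates,
        events=events,
        grs=grs,
        reference=reference,
        allele_freqs=allele_freqs,
    )


# ---------------------------------------------------------------------------
# Trial simulation

# Baseline mean/SD per outcome, on the scales the trial reports.
DEFAULT_OUTCOME_BASELINES: dict[str, tuple[float, float]] = {
    "ldl": (140.0, 38.0),
    "hdl": (53.0, 18.0),
    "total_chol": (220.0, 42.0),
    "triglycerides": (150.0, 90.0),
    "systolic_bp": (129.0, 18.0),
    "diastolic_bp": (79.0, 10.0),
    "weight": (85.0, 19.0),
    "diet_score": (3.3, 0.7),
    "activity_category": (3.6, 1.4),
    "anxiety_score": (1.7, 0.4),
    "stages_of_change": (4.0, 0.9),
    "med_beliefs_likert": (18.0, 4.0),
}

# SD of the visit-2-to-visit-3 change per outcome (per-visit noise is this
# over sqrt(2)); magnitudes follow the reported change SDs.
DEFAULT_DELTA_NOISE_SD: dict[str, float] = {
    "ldl": 28.0,
    "hdl": 9.0,
    "total_chol": 30.0,
    "triglycerides": 60.0,
    "systolic_bp": 13.0,
    "diastolic_bp": 10.0,
    "weight": 3.5,
    "diet_score": 0.8,
    "activity_category": 1.0,
    "anxiety_score": 0.45,
    "stages_of_change": 0.8,
    "med_beliefs_likert": 2.0,
}

# Item-level missing probability among attendees.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "ldl": 0.12,
    "hdl": 0.12,
    "total_chol": 0.12,
    "triglycerides": 0.12,
    "systolic_bp": 0.02,
    "diastolic_bp": 0.02,
    "weight": 0.02,
    "diet_score": 0.12,
    "activity_category": 0.10,
    "anxiety_score": 0.10,
    "stages_of_change": 0.08,
    "med_beliefs_likert": 0.08,
}

_OUTCOME_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "diet_score": (0.0, 5.0),
    "activity_category": (1.0, 6.0),
    "anxiety_score": (0.0, 5.0),
    "stages_of_change": (1.0, 5.0),
}
_NONNEGATIVE = ("ldl", "hdl", "total_chol", "triglycerides", "systolic_bp",
                "diastolic_bp", "weight", "med_beliefs_likert")


@dataclass
class TrialSimConfig:
    """Two-arm, three-visit trial generator settings (defaults are null)."""

    n_participants: int = 94
    block_size: int = 8
    weights: list[SnpWeight] = field(default_factory=load_default_weight_table)
    allele_freqs: dict[str, float] | None = None
    arm_effects: dict[str, float] = field(default_factory=dict)
    high_grs_interaction: dict[str, float] = field(default_factory=dict)
    outcome_baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_BASELINES)
    )
    delta_noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DELTA_NOISE_SD))
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    retention: tuple[float, float] = (0.82, 0.69)  # visit-2 and visit-3 attendance
    retention_grs_delta: float = 0.0  # added to GRS-arm dropout (negative retention shift)
    med_use_prob: dict[int, float] = field(default_factory=lambda: {1: 0.0, 2: 0.22, 3: 0.24})

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise SimConfigError("need at least 4 participants")
        for p in self.retention:
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"retention probability {p} outside [0, 1]")
        for name, prob in self.missingness.items():
            if not 0.0 <= prob <= 1.0:
                raise SimConfigError(f"missingness[{name}]={prob} outside [0, 1]")
        for name, (mean, sd) in self.outcome_baselines.items():
            if sd <= 0:
                raise SimConfigError(f"outcome_baselines[{name}] SD must be positive")
        for name, sd in self.delta_noise_sd.items():
            if sd <= 0:
                raise SimConfigError(f"delta_noise_sd[{name}] must be positive")
        unknown = set(self.arm_effects) - set(self.outcome_baselines)
        if unknown:
            raise SimConfigError(f"arm_effects for unknown outcomes {sorted(unknown)}")


@dataclass
class TrialData:
    ledger: TrialLedger
    genotypes: GenotypeMatrix
    grs: list[GrsResult]
    eligibility: list[EligibilityInput]
    allele_freqs: dict[str, float]


def _clip_outcome(name: str, values: np.ndarray) -> np.ndarray:
    if name in _OUTCOME_BOUNDS:
        lo, hi = _OUTCOME_BOUNDS[name]
        values = np.clip(values, lo, hi)
    elif name in _NONNEGATIVE:
        values = np.clip(values, 0.0, None)
    if name == "activity_category":
        values = np.rint(values)
    return values


def simulate_trial(
    config: TrialSimConfig,
    ref: ReferenceDistribution,
    seed: int = 0,
) -> TrialData:
    """Generate a randomized three-visit trial ledger plus genotypes.

    Participants are eligible by construction; arms come from permuted-block
    randomization; outcome trajectories are participant baseline + per-visit
    noise + the configured arm effect (applied between visits 2 and 3, GRS arm
    only) + any high-GRS interaction confined to above-median participants.
    Dropout and item missingness are missing-completely-at-random.
    """
    rng = np.random.default_rng(seed)
    n = config.n_participants
    ids = [f"P{i:03d}" for i in range(1, n + 1)]

    allele_freqs = config.allele_freqs or draw_allele_freqs(config.weights)
    genotypes = _simulate_genotypes(ids, config.weights, allele_freqs, rng)
    grs = [
        normalize_grs(r, ref)
        for r in snp_score.compute_raw_grs(genotypes, config.weights)
    ]
    percentile = {g.sample_id: g.percentile for g in grs}

    # Eligibility by construction: risks at or above the 10-year threshold.
    ethnicities = rng.choice(
        ["White", "South-Asian", "Hispanic/Latino"], size=n, p=[0.80, 0.10, 0.10]
    )
    risk10 = np.clip(rng.normal(0.11, 0.07, n), 0.06, 0.60)
    risk30 = np.clip(risk10 * rng.uniform(2.0, 3.5, n), 0.0, 0.95)
    eligibility = [
        EligibilityInput(
            risk_10yr=float(risk10[i]), risk_30yr=float(risk30[i]),
            ethnicity=str(ethnicities[i]),
        )
        for i in range(n)
    ]
    for screen in eligibility:
        result = check_eligibility(screen)
        assert result.eligible, f"construction violated eligibility: {result.reasons}"

    assignments = permuted_block_randomize(ids, block_size=config.block_size, seed=rng)
    arm_of = {a.participant_id: a.arm for a in assignments}

    r2, r3 = config.retention
    attended = {1: np.ones(n, dtype=bool)}
    is_grs = np.array([arm_of[pid] == "GRS" for pid in ids])
    for visit, base_p in ((2, r2), (3, r3)):
        p_attend = np.where(is_grs, np.clip(base_p - config.retention_grs_delta, 0, 1), base_p)
        attended[visit] = rng.random(n) < p_attend

    high = np.array([percentile[pid] is not None and percentile[pid] > 0.5 for pid in ids])

    outcome_values: dict[str, dict[int, np.ndarray]] = {}
    for name, (mean, sd) in config.outcome_baselines.items():
        person = rng.normal(mean, sd, n)
        visit_noise_sd = config.delta_noise_sd.get(name, sd / 4.0) / np.sqrt(2.0)
        effect = config.arm_effects.get(name, 0.0) * is_grs
        effect = effect + config.high_grs_interaction.get(name, 0.0) * (is_grs & high)
        per_visit = {}
        for visit in (1, 2, 3):
            values = person + rng.normal(0.0, visit_noise_sd, n)
            if visit == 3:
                values = values + effect
            per_visit[visit] = _clip_outcome(name, values)
        outcome_values[name] = per_visit

    med_flags = {
        col: {v: rng.random(n) < config.med_use_prob.get(v, 0.0) for v in (1, 2, 3)}
        for col in ("on_statin", "on_antihypertensive")
    }

    records: list[VisitRecord] = []
    for i, pid in enumerate(ids):
        for visit in (1, 2, 3):
            if not attended[visit][i]:
                records.append(VisitRecord(participant_id=pid, visit=visit, attended=False))
                continue
            kwargs: dict = {}
            for name, per_visit in outcome_values.items():
                miss_p = config.missingness.get(name, 0.0)
                if miss_p and rng.random() < miss_p:
                    continue
                value = per_visit[visit][i]
                kwargs[name] = int(value) if name == "activity_category" else float(value)
            for col, flags in med_flags.items():
                if rng.random() >= 0.05:  # med status occasionally unrecorded
                    kwargs[col] = bool(flags[visit][i])
            records.append(VisitRecord(participant_id=pid, visit=visit, attended=True, **kwargs))

    extra = pd.DataFrame(
        {
            "participant_id": ids,
            "grs_percentile": [percentile[pid] for pid in ids],
            "grs_z": [g.z_score for g in grs],
            "risk_10yr": risk10,
            "risk_30yr": risk30,
            "ethnicity": ethnicities,
        }
    )
    ledger = assemble_ledger(assignments, records, participant_extra=extra)
    return TrialData(
        ledger=ledger,
        genotypes=genotypes,
        grs=grs,
        eligibility=eligibility,
        allele_freqs=allele_freqs,
    )


# ---------------------------------------------------------------------------
# Deterministic fixture suite


def _write_vcf(path: Path, genotypes: GenotypeMatrix, weights: list[SnpWeight]) -> None:
    """Plain-text VCF mirror of a dosage matrix (ALT = effect allele)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1,length=249250621>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids),
    ]
    by_rsid = {w.rsid: w for w in weights}
    for j, rsid in enumerate(genotypes.rsids):
        w = by_rsid[rsid]
        gts = []
        for dosage in genotypes.dosages[:, j]:
            if np.isnan(dosage):
                gts.append("./.")
            else:
                alt_count = int(dosage)  # ALT carries the effect allele
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[alt_count])
        lines.append(
            f"1\t{1000 + 10 * j}\t{rsid}\t{w.other_allele}\t{w.effect_allele}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small deterministic fixture set and a checksum manifest.

    Files: the default weight table, a 10-sample genotype TSV with an
    equivalent VCF, a reference summary JSON, a 94-participant trial bundle
    (participants + visits CSV), and a pipeline config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    weights = load_default_weight_table()
    allele_freqs = draw_allele_freqs(weights, seed)

    ref_cohort = simulate_reference_cohort(
        ReferenceSimConfig(n=2000, weights=weights, allele_freqs=allele_freqs), seed=seed
    )
    ref = ref_cohort.reference

    rng = np.random.default_rng(seed + 1)
    geno_ids = [f"S{i:02d}" for i in range(1, 11)]
    genotypes = _simulate_genotypes(geno_ids, weights, allele_freqs, rng)

    trial = simulate_trial(
        TrialSimConfig(weights=weights, allele_freqs=allele_freqs), ref=ref, seed=seed + 2
    )

    paths: dict[str, Path] = {}

    weights_path = out / "weights.tsv"
    header = "rsid\teffect_allele\tother_allele\tweight\tproxy_for"
    rows = [
        f"{w.rsid}\t{w.effect_allele}\t{w.other_allele}\t{w.weight:.6g}\t{w.proxy_for}"
        for w in weights
    ]
    weights_path.write_text(header + "\n" + "\n".join(rows) + "\n")
    paths["weights"] = weights_path

    geno_path = out / "genotypes.tsv"
    frame = genotypes.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(geno_path, sep="\t", float_format="%.0f")
    paths["genotypes_tsv"] = geno_path

    vcf_path = out / "genotypes.vcf"
    _write_vcf(vcf_path, genotypes, weights)
    paths["genotypes_vcf"] = vcf_path

    ref_path = out / "reference.json"
    ref_path.write_text(
        json.dumps(
            {
                "mean_raw": ref.mean_raw,
                "sd_raw": ref.sd_raw,
                "n_ref": ref.n_ref,
                "sorted_scores": [round(float(s), 10) for s in ref.sorted_scores],
            },
            indent=1,
        )
        + "\n"
    )
    paths["reference"] = ref_path

    participants_path = out / "participants.csv"
    trial.ledger.participants.to_csv(participants_path, index=False, float_format="%.10g")
    paths["participants"] = participants_path

    visits_path = out / "visits.csv"
    trial.ledger.visits.to_csv(visits_path, index=False, float_format="%.10g")
    paths["visits"] = visits_path

    config_path = out / "config.json"
    config_path.write_text(
        json.dumps(
            {
                "seed": seed,
                "block_size": 8,
                "paths": {
                    "weights": "weights.tsv",
                    "participants": "participants.csv",
                    "visits": "visits.csv",
                    "reference": "reference.json",
                },
            },
            indent=1,
        )
        + "\n"
    )
    paths["config"] = config_path

    manifest = out / "CHECKSUMS.md"
    lines = ["# Fixture checksums (sha256)", ""]
    for name in sorted(paths):
        digest = hashlib.sha256(paths[name].read_bytes()).hexdigest()
        lines.append(f"- `{paths[name].name}`: `{digest}`")
    manifest.write_text("\n".join(lines) + "\n")
    paths["manifest"] = manifest
    return paths
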