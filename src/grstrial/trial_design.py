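"""Eligibility screening, permuted-block randomization, and the trial ledger.

Eligibility uses the two-horizon risk rule (10-year threshold inclusive,
30-year strict), an allowed-ethnicity set, and a fixed list of exclusion
flags.  Randomization allocates in permuted blocks: each block is an
independent uniform permutation of an equal number of arm labels, so
imbalance during accrual never exceeds half a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EligibilityInput",
    "EligibilityResult",
    "Assignment",
    "VisitRecord",
    "TrialLedger",
    "ARMS",
    "EXCLUSION_FLAGS",
    "DEFAULT_ALLOWED_ETHNICITIES",
    "check_eligibility",
    "permuted_block_randomize",
    "assemble_ledger",
]

ARMS = ("GRS", "SOC")
VISITS = (1, 2, 3)

# Exclusion flags a screen may carry; any set flag makes a candidate ineligible.
EXCLUSION_FLAGS = (
    "prior_mi",
    "angina",
    "cabg",
    "pci",
    "stroke",
    "peripheral_arterial_disease",
    "active_statin",
    "prior_genetic_testing",
    "limiting_condition",
    "survival_under_1yr",
)

DEFAULT_ALLOWED_ETHNICITIES = frozenset({"White", "South-Asian", "Hispanic/Latino"})

# Outcome columns a visit record may carry, with hard validity ranges
# (None = unbounded). Scores stay inside their instrument ranges.
OUTCOME_COLUMNS: dict[str, tuple[float | None, float | None]] = {
    "ldl": (0.0, None),
    "hdl": (0.0, None),
    "total_chol": (0.0, None),
    "triglycerides": (0.0, None),
    "systolic_bp": (0.0, None),
    "diastolic_bp": (0.0, None),
    "weight": (0.0, None),
    "diet_score": (0.0, 5.0),
    "activity_category": (1.0, 6.0),
    "anxiety_score": (0.0, 5.0),
    "stages_of_change": (1.0, 5.0),
    "med_beliefs_likert": (0.0, None),
}
BOOL_COLUMNS = ("on_statin", "on_antihypertensive")


@dataclass(frozen=True)
class EligibilityInput:
    risk_10yr: float
    risk_30yr: float
    ethnicity: str
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("risk_10yr", "risk_30yr"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        unknown = set(self.exclusions) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(f"unknown exclusion flags {sorted(unknown)}")


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reasons: tuple[str, ...]  # every failed criterion, empty when eligible

    def __bool__(self) -> bool:
        return self.eligible


@dataclass(frozen=True)
class Assignment:
    participant_id: str
    arm: str
    sequence_index: int
    block_index: int


@dataclass
class VisitRecord:
    """One participant-visit row; None marks a missing measurement."""

    participant_id: str
    visit: int
    attended: bool = True
    ldl: float | None = None
    hdl: float | None = None
    total_chol: float | None = None
    triglycerides: float | None = None
    systolic_bp: float | None = None
    diastolic_bp: float | None = None
    weight: float | None = None
    on_statin: bool | None = None
    on_antihypertensive: bool | None = None
    diet_score: float | None = None
    activity_category: int | None = None
    anxiety_score: float | None = None
    stages_of_change: float | None = None
    med_beliefs_likert: float | None = None

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValueError(f"visit {self.visit} not in {VISITS}")
        for name, (lo, hi) in OUTCOME_COLUMNS.items():
            value = getattr(self, name)
            if value is None:
                continue
            if (lo is not None and value < lo) or (hi is not None and value > hi):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.activity_category is not None and self.activity_category != int(self.activity_category):
            raise ValueError(f"activity_category must be integer, got {self.activity_category}")


def check_eligibility(
    screen: EligibilityInput,
    threshold_10yr: float = 0.06,
    threshold_30yr: float = 0.20,
    allowed_ethnicities: frozenset[str] | set[str] = DEFAULT_ALLOWED_ETHNICITIES,
) -> EligibilityResult:
    """Apply the risk rule (>=6% at 10 years OR >20% at 30 years), the
    ethnicity filter, and the exclusion list; reasons enumerate every failure."""
    reasons: list[str] = []
    if not (screen.risk_10yr >= threshold_10yr or screen.risk_30yr > threshold_30yr):
        reasons.append(
            f"risk below thresholds (10yr {screen.risk_10yr:.3f} < {threshold_10yr:.3f} "
            f"and 30yr {screen.risk_30yr:.3f} <= {threshold_30yr:.3f})"
        )
    if screen.ethnicity not in allowed_ethnicities:
        reasons.append(f"ethnicity {screen.ethnicity!r} not in allowed set")
    for flag in EXCLUSION_FLAGS:
        if flag in screen.exclusions:
            reasons.append(flag.replace("_", " "))
    return EligibilityResult(eligible=not reasons, reasons=tuple(reasons))


def permuted_block_randomize(
    ids: list[str],
    block_size: int = 8,
    seed: int | np.random.Generator = 0,
    arms: tuple[str, str] = ARMS,
) -> list[Assignment]:
    """Assign ids to two arms in permuted blocks.

    Each block is an independent uniform permutation of ``block_size/2``
    copies of each arm label; a trailing incomplete block takes the first
    entries of one more full permuted block.  Deterministic given the seed.
    """
    if block_size % 2 != 0 or block_size < 2:
        raise ValueError(f"block_size must be even and >= 2, got {block_size}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = block_size // 2
    template = np.array([arms[0]] * half + [arms[1]] * half)
    sequence: list[str] = []
    while len(sequence) < len(ids):
        sequence.extend(rng.permutation(template).tolist())
    return [
        Assignment(
            participant_id=pid,
            arm=sequence[i],
            sequence_index=i,
            block_index=i // block_size,
        )
        for i, pid in enumerate(ids)
    ]


@dataclass
class TrialLedger:
    """Complete (participant x visit) grid plus the arm assignments.

    ``participants`` carries one row per participant (participant_id, arm,
    sequence_index, block_index plus any extra columns such as
    grs_percentile); ``visits`` carries one row per (participant_id, visit)
    for all three visits, with ``attended`` flags and outcome columns.
    """

    participants: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self) -> None:
        expected = len(self.participants) * len(VISITS)
        if len(self.visits) != expected:
            raise ValueError(f"visit grid has {len(self.visits)} rows, expected {expected}")

    def arm_of(self) -> pd.Series:
        return self.participants.set_index("participant_id")["arm"]

    def visit_frame(self, visit: int) -> pd.DataFrame:
        frame = self.visits[self.visits["visit"] == visit]
        return frame.set_index("participant_id")

    def attrition_summary(self) -> pd.DataFrame:
        """Per-arm, per-visit attended counts and fractions."""
        merged = self.visits.merge(
            self.participants[["participant_id", "arm"]], on="participant_id"
        )
        grouped = merged.groupby(["arm", "visit"])["attended"]
        out = grouped.agg(n_attended="sum", n_total="size").reset_index()
        out["fraction"] = out["n_attended"] / out["n_total"]
        return out


def assemble_ledger(
    assignments: list[Assignment] | pd.DataFrame,
    visit_records: list[VisitRecord] | pd.DataFrame,
    participant_extra: pd.DataFrame | None = None,
) -> TrialLedger:
    """Join assignments with visit rows into a complete three-visit grid.

    Visits absent from ``visit_records`` are filled in as unattended rows;
    a record for an unassigned participant is a linkage error.
    """
    if isinstance(assignments, pd.DataFrame):
        participants = assignments.copy()
    else:
        participants = pd.DataFrame([vars(a) for a in assignments])
    if participants.empty or "participant_id" not in participants:
        raise ValueError("assignments must carry participant_id rows")
    if participants["participant_id"].duplicated().any():
        raise ValueError("duplicate participant ids in assignments")
    if participant_extra is not None:
        participants = participants.merge(participant_extra, on="participant_id", how="left")

    if isinstance(visit_records, pd.DataFrame):
        visits = visit_records.copy()
    else:
        visits = pd.DataFrame([vars(r) for r in visit_records])
    if visits.empty:
        visits = pd.DataFrame(columns=["participant_id", "visit", "attended"])

    known = set(participants["participant_id"])
    orphans = set(visits["participant_id"]) - known
    if orphans:
        raise ValueError(f"visit records for unassigned participants: {sorted(orphans)[:5]}")
    if visits.duplicated(subset=["participant_id", "visit"]).any():
        raise ValueError("duplicate (participant, visit) rows")

    grid = pd.MultiIndex.from_product(
        [participants["participant_id"], VISITS], names=["participant_id", "visit"]
    ).to_frame(index=False)
    merged = grid.merge(visits, on=["participant_id", "visit"], how="left")
    merged["attended"] = merged["attended"].eq(True)
    for col in OUTCOME_COLUMNS:
        if col not in merged:
            merged[col] = np.nan
    for col in BOOL_COLUMNS:
        if col not in merged:
            merged[col] = None
    return TrialLedger(participants=participants.reset_index(drop=True), visits=merged)
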