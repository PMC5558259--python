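"""Weighted CAD genetic risk score (GRS).

A GRS is the weighted sum, over a fixed list of risk loci, of the number of
effect alleles a sample carries; weights are per-allele log odds ratios.
This module parses SNP/weight tables, scores genotype dosage matrices, and
normalizes raw scores against a reference cohort distribution (z-score and
empirical percentile).

Dosages entering this module always count EFFECT alleles; any allele
flipping against a genotype file's REF/ALT orientation happens in
:mod:`grstrial.cli_io` before a matrix is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SnpWeight",
    "GenotypeMatrix",
    "ReferenceDistribution",
    "GrsResult",
    "WeightTableError",
    "MissingGenotypeError",
    "DegenerateReferenceError",
    "load_weight_table",
    "load_default_weight_table",
    "compute_raw_grs",
    "fit_reference",
    "normalize_grs",
    "score_samples",
]

_VALID_BASES = frozenset("ACGT")

DEFAULT_WEIGHT_RESOURCE = "cad19_weights.tsv"


class WeightTableError(ValueError):
    """Raised for malformed or inconsistent SNP/weight tables."""


class MissingGenotypeError(KeyError):
    """Raised when a scored locus has no genotype and policy is ``error``."""


class DegenerateReferenceError(ValueError):
    """Raised when a reference distribution cannot be fitted (n < 2 or SD 0)."""


@dataclass(frozen=True)
class SnpWeight:
    """One locus of the score: identifier, allele orientation and log-OR weight."""

    rsid: str
    effect_allele: str
    other_allele: str
    weight: float
    proxy_for: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise WeightTableError("rsid must be non-empty")
        for label, allele in (("effect", self.effect_allele), ("other", self.other_allele)):
            if allele not in _VALID_BASES:
                raise WeightTableError(
                    f"{self.rsid}: {label} allele {allele!r} is not a single base in ACGT"
                )
        if self.effect_allele == self.other_allele:
            raise WeightTableError(f"{self.rsid}: effect and other allele are identical")
        if not math.isfinite(self.weight):
            raise WeightTableError(f"{self.rsid}: weight {self.weight!r} is not finite")

    @property
    def is_ambiguous(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) allele pairs."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class GenotypeMatrix:
    """Per-(sample, rsid) effect-allele dosages in {0, 1, 2}; NaN marks missing."""

    sample_ids: list[str]
    rsids: list[str]
    dosages: np.ndarray  # float array, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.rsids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.rsids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.rsids)) != len(self.rsids):
            raise ValueError("duplicate rsids")
        present = self.dosages[~np.isnan(self.dosages)]
        if present.size and not np.isin(present, (0.0, 1.0, 2.0)).all():
            bad = present[~np.isin(present, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages outside {{0,1,2}}: {bad[:5]!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self.rsids.index(rsid)]

    @classmethod
    def concat(cls, a: "GenotypeMatrix", b: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two matrices over samples; rsid lists must match as sets."""
        if set(a.rsids) != set(b.rsids):
            raise ValueError("rsid sets differ; cannot concatenate")
        order = [b.rsids.index(r) for r in a.rsids]
        return cls(
            sample_ids=a.sample_ids + b.sample_ids,
            rsids=list(a.rsids),
            dosages=np.vstack([a.dosages, b.dosages[:, order]]),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        """Build from a samples-as-rows, rsids-as-columns DataFrame."""
        return cls(
            sample_ids=[str(s) for s in frame.index],
            rsids=[str(c) for c in frame.columns],
            dosages=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.rsids)


@dataclass(frozen=True)
class ReferenceDistribution:
    """Summary of the raw-GRS distribution in a reference cohort."""

    mean_raw: float
    sd_raw: float
    n_ref: int
    sorted_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_ref < 2:
            raise DegenerateReferenceError(f"reference needs n >= 2, got {self.n_ref}")
        if not (self.sd_raw > 0 and math.isfinite(self.sd_raw)):
            raise DegenerateReferenceError(f"reference SD must be positive, got {self.sd_raw}")
        if self.sorted_scores is not None:
            scores = np.asarray(self.sorted_scores, dtype=float)
            if scores.shape != (self.n_ref,):
                raise DegenerateReferenceError(
                    f"sorted_scores length {scores.shape} != n_ref {self.n_ref}"
                )
            if np.any(np.diff(scores) < 0):
                raise DegenerateReferenceError("sorted_scores must be nondecreasing")
            object.__setattr__(self, "sorted_scores", scores)


@dataclass(frozen=True)
class GrsResult:
    """Scored sample: raw weighted score, allele count, and normalized placement.

    ``allele_count`` is an integer unless missing loci were mean-imputed, in
    which case fractional expected counts enter the sum and
    ``n_missing_imputed`` records how many loci were filled.
    """

    sample_id: str
    raw_score: float
    allele_count: float
    z_score: float | None = None
    percentile: float | None = None
    n_missing_imputed: int = 0


def _parse_weight_frame(frame: pd.DataFrame, source: str) -> list[SnpWeight]:
    required = ["rsid", "effect_allele", "other_allele", "weight"]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise WeightTableError(f"{source}: missing columns {missing_cols}")
    if "proxy_for" not in frame.columns:
        frame = frame.assign(proxy_for="")
    weights: list[SnpWeight] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        rsid = str(row.rsid).strip()
        if rsid in seen:
            raise WeightTableError(f"{source}: duplicate rsid {rsid}")
        seen.add(rsid)
        raw_weight = row.weight
        if pd.isna(raw_weight):
            raise WeightTableError(f"{source}: {rsid} has no weight")
        proxy = "" if pd.isna(row.proxy_for) else str(row.proxy_for).strip()
        weights.append(
            SnpWeight(
                rsid=rsid,
                effect_allele=str(row.effect_allele).strip().upper(),
                other_allele=str(row.other_allele).strip().upper(),
                weight=float(raw_weight),
                proxy_for=proxy,
            )
        )
    return weights


def load_weight_table(path: str | Path) -> list[SnpWeight]:
    """Parse a TSV weight table (columns rsid, effect_allele, other_allele,
    weight, proxy_for; ``#`` comment lines allowed) into validated entries."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise WeightTableError(f"{path}: no header found") from exc
    if frame.empty:
        return []
    frame["weight"] = pd.to_numeric(frame["weight"], errors="coerce") if "weight" in frame else np.nan
    return _parse_weight_frame(frame, str(path))


def load_default_weight_table() -> list[SnpWeight]:
    """Load the bundled default 19-locus table (placeholder-documented weights)."""
    ref = resources.files("grstrial.data").joinpath(DEFAULT_WEIGHT_RESOURCE)
    with resources.as_file(ref) as path:
        return load_weight_table(path)


def compute_raw_grs(
    genotypes: GenotypeMatrix,
    weights: Sequence[SnpWeight],
    missing_policy: str = "error",
    effect_allele_freqs: dict[str, float] | None = None,
) -> list[GrsResult]:
    """Compute raw weighted scores and risk-allele counts for every sample.

    ``missing_policy='mean_impute'`` replaces a missing dosage with twice the
    configured effect-allele frequency for that locus and counts the fill in
    ``n_missing_imputed``; the default policy refuses missing data.
    """
    if not weights:
        raise WeightTableError("empty weight table; nothing to score")
    if missing_policy not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    n = genotypes.n_samples
    dosage = np.full((n, len(weights)), np.nan)
    col_of = {rsid: j for j, rsid in enumerate(genotypes.rsids)}
    for i, w in enumerate(weights):
        j = col_of.get(w.rsid)
        if j is not None:
            dosage[:, i] = genotypes.dosages[:, j]
        elif missing_policy == "error":
            raise MissingGenotypeError(f"no genotypes for scored locus {w.rsid}")

    missing = np.isnan(dosage)
    if missing.any():
        if missing_policy == "error":
            bad = [weights[i].rsid for i in np.unique(np.where(missing)[1])]
            raise MissingGenotypeError(f"missing dosages at {bad} under policy=error")
        freqs = effect_allele_freqs or {}
        for i, w in enumerate(weights):
            col_missing = missing[:, i]
            if not col_missing.any():
                continue
            if w.rsid not in freqs:
                raise MissingGenotypeError(
                    f"mean imputation for {w.rsid} needs a configured effect-allele frequency"
                )
            dosage[col_missing, i] = 2.0 * float(freqs[w.rsid])

    wvec = np.array([w.weight for w in weights])
    raw = dosage @ wvec
    counts = dosage.sum(axis=1)
    n_imputed = missing.sum(axis=1)
    return [
        GrsResult(
            sample_id=sid,
            raw_score=float(raw[k]),
            allele_count=float(counts[k]),
            n_missing_imputed=int(n_imputed[k]),
        )
        for k, sid in enumerate(genotypes.sample_ids)
    ]


def fit_reference(scores: Iterable[float]) -> ReferenceDistribution:
    """Fit mean/SD (n-1 denominator) and retain the sorted empirical scores."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise DegenerateReferenceError(f"need >=2 reference scores, got {arr.size}")
    if not np.isfinite(arr).all():
        raise DegenerateReferenceError("non-finite reference scores")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise DegenerateReferenceError("reference scores have zero variance")
    return ReferenceDistribution(
        mean_raw=float(arr.mean()),
        sd_raw=sd,
        n_ref=int(arr.size),
        sorted_scores=np.sort(arr),
    )


def normalize_grs(result: GrsResult, ref: ReferenceDistribution) -> GrsResult:
    """Fill z-score and percentile (fraction of reference strictly below)."""
    z = (result.raw_score - ref.mean_raw) / ref.sd_raw
    if ref.sorted_scores is not None:
        below = int(np.searchsorted(ref.sorted_scores, result.raw_score, side="left"))
        pct = below / ref.n_ref
    else:
        pct = float(norm.cdf(z))
    return replace(result, z_score=float(z), percentile=float(pct))


def score_samples(
    genotypes: GenotypeMatrix,
    weights: Sequence[SnpWeight],
    ref: ReferenceDistribution | None = None,
    missing_policy: str = "error",
    effect_allele_freqs: dict[str, float] | None = None,
) -> list[GrsResult]:
    """Convenience: raw scores plus normalization when a reference is given."""
    results = compute_raw_grs(genotypes, weights, missing_policy, effect_allele_freqs)
    if ref is not None:
        results = [normalize_grs(r, ref) for r in results]
    return results
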