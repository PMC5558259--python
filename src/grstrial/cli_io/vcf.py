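"""Genotype readers: VCF (rsid-keyed, allele-flipping) and sample x SNP TSV.

The scoring module only ever sees effect-allele dosages; this adapter owns
REF/ALT orientation.  A record whose alleles match neither orientation of the
weight table, or that is multiallelic at a scored locus, becomes missing with
a logged warning.  Strand-ambiguous (A/T, C/G) loci are used with a warning
by default and can be dropped instead.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ..snp_score import GenotypeMatrix, SnpWeight

logger = logging.getLogger(__name__)

__all__ = ["read_genotypes_vcf", "read_genotypes_tsv", "VcfFormatError"]


class VcfFormatError(ValueError):
    """Malformed VCF input."""


def _alt_dosage(genotype: list) -> float:
    """Count ALT alleles in one cyvcf2 genotype entry; NaN when any missing."""
    alleles = genotype[:-1]  # last element is the phasing flag
    if any(a is None or a < 0 for a in alleles):
        return np.nan
    return float(sum(1 for a in alleles if a == 1))


def read_genotypes_vcf(
    path: str | Path,
    weights: Sequence[SnpWeight],
    ambiguous_policy: str = "warn",
) -> GenotypeMatrix:
    """Read effect-allele dosages at the weight-table loci from a VCF."""
    if ambiguous_policy not in ("warn", "drop"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    by_rsid = {w.rsid: w for w in weights}
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfFormatError(f"{path}: cannot open as VCF ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF carries no samples")

    dosage = {}
    try:
        for variant in vcf:
            w = by_rsid.get(variant.ID)
            if w is None:
                continue
            if len(variant.ALT) != 1:
                logger.warning("%s: multiallelic at scored locus %s; set missing", path, w.rsid)
                dosage[w.rsid] = np.full(len(samples), np.nan)
                continue
            ref, alt = variant.REF.upper(), variant.ALT[0].upper()
            alt_counts = np.array([_alt_dosage(g) for g in variant.genotypes])
            if (ref, alt) == (w.other_allele, w.effect_allele):
                values = alt_counts
            elif (ref, alt) == (w.effect_allele, w.other_allele):
                values = 2.0 - alt_counts
            else:
                logger.warning(
                    "%s: alleles %s/%s at %s match neither orientation of %s/%s; set missing",
                    path, ref, alt, w.rsid, w.effect_allele, w.other_allele,
                )
                dosage[w.rsid] = np.full(len(samples), np.nan)
                continue
            if w.is_ambiguous:
                if ambiguous_policy == "drop":
                    logger.warning("%s: strand-ambiguous locus %s dropped", path, w.rsid)
                    dosage[w.rsid] = np.full(len(samples), np.nan)
                    continue
                logger.warning("%s: strand-ambiguous locus %s used as-is", path, w.rsid)
            dosage[w.rsid] = values
    except Exception as exc:
        if isinstance(exc, VcfFormatError):
            raise
        raise VcfFormatError(f"{path}: parse failure ({exc})") from exc

    rsids = [w.rsid for w in weights if w.rsid in dosage]
    matrix = (
        np.column_stack([dosage[r] for r in rsids])
        if rsids
        else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(sample_ids=samples, rsids=rsids, dosages=matrix)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a samples-as-rows, rsids-as-columns dosage TSV (0/1/2/NA cells)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return GenotypeMatrix.from_frame(frame.astype(float))
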