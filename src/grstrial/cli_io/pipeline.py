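"""End-to-end pipeline: score -> normalize -> risks -> design -> analysis.

``run_pipeline`` consumes a :class:`PipelineConfig` whose ``paths`` point at
the input files (weight table, genotypes as TSV or VCF, a reference summary,
participant assignments and visit records) and writes scored results, the
outcome report, the subgroup reports, and a reproducibility log into the
output directory.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..outcome_stats import OutcomeReport, analyze_outcomes, subgroup_analysis
from ..snp_score import (
    GenotypeMatrix,
    ReferenceDistribution,
    fit_reference,
    load_default_weight_table,
    load_weight_table,
    score_samples,
)
from ..trial_design import BOOL_COLUMNS, TrialLedger, assemble_ledger, permuted_block_randomize
from .config import ConfigError, PipelineConfig
from .vcf import read_genotypes_tsv, read_genotypes_vcf

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError", "read_reference_json", "read_visits_csv"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def read_reference_json(path: str | Path) -> ReferenceDistribution:
    raw = json.loads(Path(path).read_text())
    scores = raw.get("sorted_scores")
    return ReferenceDistribution(
        mean_raw=float(raw["mean_raw"]),
        sd_raw=float(raw["sd_raw"]),
        n_ref=int(raw["n_ref"]),
        sorted_scores=np.asarray(scores, dtype=float) if scores is not None else None,
    )


def read_visits_csv(path: str | Path) -> pd.DataFrame:
    """Read a visits CSV, coercing boolean-ish columns written by pandas."""
    frame = pd.read_csv(path)
    bool_map = {True: True, False: False, "True": True, "False": False, "true": True, "false": False}
    for col in ("attended", *BOOL_COLUMNS):
        if col in frame.columns:
            frame[col] = frame[col].map(bool_map)
    frame["attended"] = frame["attended"].eq(True)
    return frame


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _risk_table(
    cov_path: Path, config: PipelineConfig, grs_frame: pd.DataFrame | None
) -> pd.DataFrame:
    """Per-row 10/30-year risks, genetically updated risk, and eligibility."""
    from ..risk_engine import RiskProfile, framingham_10yr, framingham_30yr, update_risk
    from ..trial_design import EligibilityInput, check_eligibility

    frame = pd.read_csv(cov_path)
    z_by_id = {}
    if grs_frame is not None:
        z_by_id = dict(zip(grs_frame["sample_id"], grs_frame["z_score"]))
    rows = []
    for rec in frame.to_dict(orient="records"):
        profile = RiskProfile(
            age=float(rec["age"]),
            sex=str(rec["sex"]),
            total_chol=float(rec["total_chol"]),
            hdl_chol=float(rec["hdl_chol"]),
            systolic_bp=float(rec["systolic_bp"]),
            bp_treated=bool(rec.get("bp_treated", False)),
            smoker=bool(rec.get("smoker", False)),
            diabetes=bool(rec.get("diabetes", False)),
        )
        r10 = framingham_10yr(profile, config.framingham_variant)
        r30 = framingham_30yr(profile)
        sid = rec.get("sample_id", rec.get("participant_id"))
        z = rec.get("z", z_by_id.get(sid))
        z = float(z) if z is not None and pd.notna(z) else 0.0
        updated = update_risk(r10, config.rr_per_sd, z, cap=config.risk_cap)
        elig = check_eligibility(
            EligibilityInput(
                risk_10yr=r10, risk_30yr=r30,
                ethnicity=str(rec.get("ethnicity", "White")),
            ),
            threshold_10yr=config.eligibility_10yr,
            threshold_30yr=config.eligibility_30yr,
            allowed_ethnicities=frozenset(config.allowed_ethnicities),
        )
        rows.append(
            {
                "sample_id": sid,
                "risk_10yr": r10,
                "risk_30yr": r30,
                "z": z,
                "genetic_rr": updated.genetic_rr,
                "updated_10yr": updated.updated_10yr,
                "capped": updated.capped,
                "eligible": elig.eligible,
                "reasons": "; ".join(elig.reasons),
            }
        )
    return pd.DataFrame(rows)


def _report_payload(report: OutcomeReport) -> dict:
    frame = report.to_frame()
    return {
        "subgroup": report.subgroup,
        "comparison_count": report.comparison_count,
        "rows": json.loads(frame.to_json(orient="records")),
    }


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, base_dir: str | Path | None = None
) -> dict:
    """Execute the configured pipeline; return the run log as a dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # -- weights -----------------------------------------------------------
    weights_path = config.resolve_path("weights", base_dir)
    weights = (
        load_weight_table(weights_path) if weights_path else load_default_weight_table()
    )
    if not weights:
        raise PipelineError("stage 'weights' failed: empty weight table")
    counts["loci"] = len(weights)

    # -- genotypes ---------------------------------------------------------
    genotypes: GenotypeMatrix | None = None
    tsv_path = config.resolve_path("genotypes", base_dir)
    vcf_path = config.resolve_path("genotypes_vcf", base_dir)
    load_geno = _stage("genotypes")(
        lambda: read_genotypes_tsv(tsv_path)
        if tsv_path
        else read_genotypes_vcf(vcf_path, weights, config.ambiguous_policy)
    )
    if tsv_path or vcf_path:
        genotypes = load_geno()
        counts["samples_genotyped"] = genotypes.n_samples

    # -- reference + scoring ----------------------------------------------
    grs_frame = None
    if genotypes is not None:
        ref_path = config.resolve_path("reference", base_dir)
        if ref_path:
            reference = _stage("reference")(read_reference_json)(ref_path)
        else:
            logger.info("no reference summary given; normalizing against this batch")
            raw = _stage("score")(score_samples)(
                genotypes, weights, missing_policy=config.missing_policy
            )
            reference = fit_reference([r.raw_score for r in raw])
        results = _stage("score")(score_samples)(
            genotypes, weights, ref=reference, missing_policy=config.missing_policy
        )
        grs_frame = pd.DataFrame([asdict(r) for r in results])
        grs_frame.to_csv(out / "grs.csv", index=False, float_format="%.10g")
        counts["samples_scored"] = len(grs_frame)

    # -- risks and eligibility (optional covariates file) ------------------
    cov_path = config.resolve_path("covariates", base_dir)
    if cov_path is not None:
        risk_frame = _stage("risk")(_risk_table)(cov_path, config, grs_frame)
        risk_frame.to_csv(out / "risk.csv", index=False, float_format="%.10g")
        counts["screened"] = len(risk_frame)
        counts["eligible"] = int(risk_frame["eligible"].sum())

    # -- assignments (ingest or randomize) ---------------------------------
    participants_path = config.resolve_path("participants", base_dir)
    participants = None
    if participants_path:
        participants = _stage("assignments")(pd.read_csv)(participants_path)
    elif genotypes is not None:
        assignments = permuted_block_randomize(
            list(genotypes.sample_ids), block_size=config.block_size, seed=config.seed
        )
        participants = pd.DataFrame([vars(a) for a in assignments])
        if grs_frame is not None:
            participants = participants.merge(
                grs_frame[["sample_id", "z_score", "percentile"]].rename(
                    columns={
                        "sample_id": "participant_id",
                        "z_score": "grs_z",
                        "percentile": "grs_percentile",
                    }
                ),
                on="participant_id",
                how="left",
            )
    if participants is not None:
        participants.to_csv(out / "assignments.csv", index=False, float_format="%.10g")
        counts["randomized"] = len(participants)

    # -- outcome analysis --------------------------------------------------
    reports: list[OutcomeReport] = []
    visits_path = config.resolve_path("visits", base_dir)
    if visits_path is not None:
        if participants is None:
            raise PipelineError("stage 'analysis' failed: visits given without assignments")
        visits = _stage("analysis")(read_visits_csv)(visits_path)
        ledger = _stage("analysis")(assemble_ledger)(participants, visits)
        report = _stage("analysis")(analyze_outcomes)(
            ledger,
            outcome_rows=[tuple(p) for p in config.outcomes],
            alpha=config.alpha,
        )
        reports.append(report)
        counts["outcome_rows"] = len(report.rows)
        for name in config.subgroups:
            try:
                reports.append(
                    subgroup_analysis(
                        ledger,
                        name,
                        percentile_threshold=config.subgroup_percentile,
                        alpha=config.alpha,
                    )
                )
            except Exception as exc:
                logger.warning("subgroup %s skipped: %s", name, exc)
                counts[f"subgroup_{name}_skipped"] = 1
        for rep in reports:
            suffix = f"_{rep.subgroup}" if rep.subgroup else ""
            rep.to_frame().to_csv(
                out / f"report{suffix}.csv", index=False, float_format="%.10g"
            )
        payload = [_report_payload(rep) for rep in reports]
        (out / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        for rep in reports:
            label = rep.subgroup or "full"
            counts[f"analyzed_rows_{label}"] = sum(1 for r in rep.rows if r.error is None)

    run_log = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "bundled_tables": {
            "weights": "cad19_weights.tsv" if not config.resolve_path("weights", base_dir) else str(weights_path),
            "framingham_10yr": "framingham_10yr_cvd.json",
            "framingham_30yr": "framingham_30yr_cvd.json",
        },
        "counts": counts,
        "config": json.loads(config.to_json()),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True) + "\n")
    return run_log
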