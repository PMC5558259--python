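"""Framingham-style risk equations, relative-risk regression, and genetic updating.

The risk equations are coefficient-table-driven: a JSON table supplies, per
sex, covariate names, transforms (identity or log), betas, and either a
published mean linear predictor or per-covariate means, plus the baseline
survival at the horizon.  Two tables ship with the package:

* ``framingham_10yr_cvd.json`` — 10-year risk of the form
  ``1 - S0 ** exp(lp - lp_mean)``;
* ``framingham_30yr_cvd.json`` — 30-year risk in a competing-risk form where
  the event and competing-death blocks are reduced to constant hazards from
  their 30-year baseline survivals.

The relative-risk regression is a log-link binomial GLM of incident events on
GRS z-score adjusted for age and sex, with robust (sandwich) standard errors
and a robust-Poisson fallback on non-convergence.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "RiskProfile",
    "RrFit",
    "UpdatedRisk",
    "RrFitError",
    "load_coefficient_table",
    "framingham_10yr",
    "framingham_30yr",
    "fit_rr_regression",
    "update_risk",
]

BUNDLED_TABLES = {
    "10yr": "framingham_10yr_cvd.json",
    "30yr": "framingham_30yr_cvd.json",
}


class RrFitError(RuntimeError):
    """Relative-risk regression failed (separation, non-convergence, no events)."""


@dataclass(frozen=True)
class RiskProfile:
    """Covariates of the sex-specific risk equations."""

    age: float
    sex: str
    total_chol: float
    hdl_chol: float
    systolic_bp: float
    bp_treated: bool = False
    smoker: bool = False
    diabetes: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 20 <= self.age <= 100:
            raise ValueError(f"age {self.age} outside [20, 100]")
        for name in ("total_chol", "hdl_chol", "systolic_bp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def covariate(self, name: str) -> float:
        value = getattr(self, name)
        return float(value) if not isinstance(value, bool) else float(bool(value))


@dataclass(frozen=True)
class RrFit:
    """Fitted relative risk per 1 SD of GRS with robust 95% CI."""

    beta_per_sd: float
    se_beta: float
    rr_per_sd: float
    ci_low: float
    ci_high: float
    model: str = "log_binomial"
    n: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        assert math.isclose(self.rr_per_sd, math.exp(self.beta_per_sd), rel_tol=1e-12)
        if not self.ci_low <= self.rr_per_sd <= self.ci_high:
            raise ValueError("CI does not bracket the point estimate")


@dataclass(frozen=True)
class UpdatedRisk:
    """Baseline 10-year risk multiplied by the genetic relative risk, capped."""

    base_10yr: float
    genetic_rr: float
    updated_10yr: float
    capped: bool


def load_coefficient_table(source: str | Path | Mapping[str, Any]) -> dict:
    """Load a coefficient table from a bundled name ('10yr'/'30yr'), a JSON
    path, or an already-parsed mapping."""
    if isinstance(source, Mapping):
        table = dict(source)
    elif str(source) in BUNDLED_TABLES:
        ref = resources.files("grstrial.data").joinpath(BUNDLED_TABLES[str(source)])
        table = json.loads(ref.read_text())
    else:
        table = json.loads(Path(source).read_text())
    if "sex" not in table or "model" not in table:
        raise ValueError("coefficient table needs 'model' and per-'sex' blocks")
    return table


def _transform(value: float, how: str) -> float:
    if how == "identity":
        return value
    if how == "log":
        if value <= 0:
            raise ValueError(f"log transform of non-positive value {value}")
        return math.log(value)
    raise ValueError(f"unknown transform {how!r}")


def _applies(cov: Mapping[str, Any], profile: RiskProfile) -> bool:
    when = cov.get("when")
    if when is None:
        return True
    if when == "bp_treated":
        return profile.bp_treated
    if when == "bp_untreated":
        return not profile.bp_treated
    raise ValueError(f"unknown condition {when!r}")


def _linear_predictor(block: Mapping[str, Any], profile: RiskProfile) -> tuple[float, float]:
    """Return (lp, lp_mean) for one per-sex coefficient block."""
    lp = 0.0
    lp_mean_acc = 0.0
    for cov in block["covariates"]:
        beta = float(cov["beta"])
        if "mean" in cov:
            lp_mean_acc += beta * _transform(float(cov["mean"]), cov.get("transform", "identity"))
        if not _applies(cov, profile):
            continue
        value = profile.covariate(cov["name"])
        rng = cov.get("range")
        if rng is not None and not rng[0] <= value <= rng[1]:
            logger.warning(
                "covariate %s=%.4g outside supported range %s; value still used",
                cov["name"], value, rng,
            )
        lp += beta * _transform(value, cov.get("transform", "identity"))
    lp_mean = float(block["lp_mean"]) if "lp_mean" in block else lp_mean_acc
    return lp, lp_mean


def framingham_10yr(profile: RiskProfile, coeffs: str | Path | Mapping[str, Any] = "10yr") -> float:
    """10-year risk ``1 - S0 ** exp(lp - lp_mean)`` from the per-sex table."""
    table = load_coefficient_table(coeffs)
    if table["model"] != "baseline_survival":
        raise ValueError(f"expected a baseline_survival table, got {table['model']!r}")
    block = table["sex"][profile.sex]
    lp, lp_mean = _linear_predictor(block, profile)
    s0 = float(block["baseline_survival"])
    risk = 1.0 - s0 ** math.exp(lp - lp_mean)
    return min(max(risk, 0.0), 1.0)


def framingham_30yr(profile: RiskProfile, coeffs: str | Path | Mapping[str, Any] = "30yr") -> float:
    """30-year event risk under competing mortality.

    Each block's 30-year baseline survival is converted to a constant baseline
    hazard ``lambda0 = -ln(S0)/horizon``; proportional scaling by
    ``exp(lp - lp_mean)`` gives per-profile hazards, and the event cumulative
    incidence is ``le/(le+ld) * (1 - exp(-(le+ld)*horizon))``.
    """
    table = load_coefficient_table(coeffs)
    if table["model"] != "competing_exponential":
        raise ValueError(f"expected a competing_exponential table, got {table['model']!r}")
    horizon = float(table.get("horizon_years", 30))
    blocks = table["sex"][profile.sex]
    hazards = {}
    for kind in ("event", "death"):
        block = blocks[kind]
        lp, lp_mean = _linear_predictor(block, profile)
        lambda0 = -math.log(float(block["baseline_survival"])) / horizon
        hazards[kind] = lambda0 * math.exp(lp - lp_mean)
    le, ld = hazards["event"], hazards["death"]
    total = le + ld
    if total <= 0:
        return 0.0
    risk = le / total * (1.0 - math.exp(-total * horizon))
    return min(max(risk, 0.0), 1.0)


def _design(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    required = {"event", "z", "age", "sex"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns {sorted(missing)}")
    y = cohort["event"].astype(float).to_numpy()
    z = cohort["z"].astype(float).to_numpy()
    if not np.isfinite(z).all():
        raise ValueError("non-finite z scores in cohort")
    sex = cohort["sex"]
    male = (sex == "male").astype(float).to_numpy() if sex.dtype == object else sex.astype(float).to_numpy()
    X = np.column_stack([np.ones(len(y)), z, cohort["age"].astype(float).to_numpy(), male])
    return y, X


def fit_rr_regression(cohort: pd.DataFrame) -> RrFit:
    """Fit event ~ z + age + sex with a log link; return the per-SD RR.

    The primary fit is a log-binomial GLM; if it fails to converge (or walks
    out of the parameter space) a robust-Poisson fit is used instead.  95% CIs
    come from HC1 sandwich standard errors in both cases.
    """
    y, X = _design(cohort)
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise RrFitError(f"degenerate cohort: {n_events} events of {len(y)}")

    start = np.array([math.log(max(y.mean(), 1e-12)), 0.0, 0.0, 0.0])
    res = None
    model_name = "log_binomial"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log()))
            res = glm.fit(start_params=start, maxiter=200, cov_type="HC1")
            if not res.converged or not np.isfinite(res.params).all():
                res = None
        except Exception:
            res = None
        if res is None:
            model_name = "poisson_robust"
            try:
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200, cov_type="HC1")
            except Exception as exc:  # pragma: no cover - double failure is pathological
                raise RrFitError(f"both log-binomial and Poisson fits failed: {exc}") from exc
            if not res.converged or not np.isfinite(res.params).all():
                raise RrFitError("relative-risk regression did not converge (possible separation)")

    beta = float(res.params[1])
    se = float(res.bse[1])
    zcrit = float(norm.ppf(0.975))
    return RrFit(
        beta_per_sd=beta,
        se_beta=se,
        rr_per_sd=math.exp(beta),
        ci_low=math.exp(beta - zcrit * se),
        ci_high=math.exp(beta + zcrit * se),
        model=model_name,
        n=len(y),
        n_events=n_events,
    )


def update_risk(base_10yr: float, fit: RrFit | float, z: float, cap: float = 1.0) -> UpdatedRisk:
    """Multiply the base 10-year risk by ``exp(beta_per_sd * z)``, capping.

    ``fit`` may be an :class:`RrFit` or a bare relative risk per SD.
    """
    if not 0.0 <= base_10yr <= 1.0:
        raise ValueError(f"base risk {base_10yr} outside [0, 1]")
    if not 0.0 < cap <= 1.0:
        raise ValueError(f"cap {cap} outside (0, 1]")
    beta = fit.beta_per_sd if isinstance(fit, RrFit) else math.log(float(fit))
    genetic_rr = math.exp(beta * z)
    raw = base_10yr * genetic_rr
    capped = raw > cap
    return UpdatedRisk(
        base_10yr=base_10yr,
        genetic_rr=genetic_rr,
        updated_10yr=min(raw, cap),
        capped=capped,
    )
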