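"""Pipeline configuration: JSON-backed, validated, hashable for run logs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from ..outcome_stats import DEFAULT_REPORT_ROWS, OUTCOMES
from ..trial_design import DEFAULT_ALLOWED_ETHNICITIES

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Every tunable constant of the end-to-end pipeline, with the defaults
    used throughout: 6% 10-year / 20% 30-year eligibility thresholds, blocks
    of 8, the 50th-percentile subgroup cut, alpha 0.05, risk cap 1.0."""

    seed: int = 0
    block_size: int = 8
    eligibility_10yr: float = 0.06
    eligibility_30yr: float = 0.20
    subgroup_percentile: float = 0.5
    alpha: float = 0.05
    risk_cap: float = 1.0
    rr_per_sd: float = 1.18
    framingham_variant: str = "10yr"
    missing_policy: str = "error"
    ambiguous_policy: str = "warn"
    allowed_ethnicities: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_ALLOWED_ETHNICITIES)
    )
    outcomes: list[list[str]] = field(
        default_factory=lambda: [list(pair) for pair in DEFAULT_REPORT_ROWS]
    )
    subgroups: list[str] = field(
        default_factory=lambda: ["high_grs", "positive_med_attitude"]
    )
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.block_size % 2 != 0 or self.block_size < 2:
            raise ConfigError(f"block_size must be even and >= 2, got {self.block_size}")
        for name, lo, hi in (
            ("eligibility_10yr", 0.0, 1.0),
            ("eligibility_30yr", 0.0, 1.0),
            ("subgroup_percentile", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ConfigError(f"{name}={value} outside [{lo}, {hi}]")
        if not 0.0 < self.risk_cap <= 1.0:
            raise ConfigError(f"risk_cap={self.risk_cap} outside (0, 1]")
        if self.rr_per_sd <= 0:
            raise ConfigError("rr_per_sd must be positive")
        if self.missing_policy not in ("error", "mean_impute"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")
        if self.ambiguous_policy not in ("warn", "drop"):
            raise ConfigError(f"unknown ambiguous_policy {self.ambiguous_policy!r}")
        for pair in self.outcomes:
            if len(pair) != 2 or pair[0] not in OUTCOMES or pair[1] not in (
                "imputation", "no_imputation"
            ):
                raise ConfigError(f"bad outcome row {pair!r}")
        for sub in self.subgroups:
            if sub not in ("high_grs", "positive_med_attitude"):
                raise ConfigError(f"unknown subgroup {sub!r}")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def resolve_path(self, key: str, base: str | Path | None = None) -> Path | None:
        value = self.paths.get(key)
        if value is None:
            return None
        path = Path(value)
        if not path.is_absolute() and base is not None:
            path = Path(base) / path
        return path
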