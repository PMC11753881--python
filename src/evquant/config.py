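"""Run configuration: defaults, YAML file, command-line overrides.

Precedence is CLI > config file > defaults; :meth:`RunConfig.with_overrides`
applies only non-None values so absent CLI flags fall through to the file
or the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and stage options shared by the command-line stages."""

    log2fc_cutoff: float = 0.58  # |log2 fold change| for enrichment calls (~1.5x)
    p_cutoff: float = 0.05
    eccentricity_cutoff: float = 0.5
    min_valid_values: int = 2  # per-group valid values to call a protein identified
    bin_width_nm: float = 1.0
    smooth_window: int = 5
    peak_prominence_fraction: float = 0.1
    downshift_sd: float = 1.8
    width_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log2fc_cutoff <= 0:
            raise ConfigurationError("log2fc_cutoff must be positive")
        if not (0 < self.p_cutoff < 1):
            raise ConfigurationError("p_cutoff must lie in (0, 1)")
        if not (0 <= self.eccentricity_cutoff < 1):
            raise ConfigurationError("eccentricity_cutoff must lie in [0, 1)")
        if self.min_valid_values < 1:
            raise ConfigurationError("min_valid_values must be >= 1")
        if self.bin_width_nm <= 0:
            raise ConfigurationError("bin_width_nm must be positive")
        if self.smooth_window < 1:
            raise ConfigurationError("smooth_window must be >= 1")
        if not (0 <= self.peak_prominence_fraction <= 1):
            raise ConfigurationError("peak_prominence_fraction must lie in [0, 1]")
        if self.downshift_sd < 0 or self.width_sd < 0:
            raise ConfigurationError("imputation shifts must be >= 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **overrides: Any) -> "RunConfig":
        """Apply non-None overrides (CLI flags) on top of this config."""
        updates = {k: v for k, v in overrides.items() if v is not None}
        return replace(self, **updates) if updates else self


def load_config(path: Optional[Union[str, Path]] = None, **overrides: Any) -> RunConfig:
    base = RunConfig.from_yaml(path) if path else RunConfig()
    return base.with_overrides(**overrides)
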