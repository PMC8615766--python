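"""Run configuration: thresholds, fit options and the global sign convention.

A single YAML file (all keys optional, unknown keys rejected) controls
the applicability thresholds, the fitting options and the phase
convention switch, so that a full pipeline run is reproducible from
the config plus the seed alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .fitting import FitOptions
from .signal_processing import HysteresisThresholds

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Unknown or invalid configuration keys."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    thresholds: HysteresisThresholds = HysteresisThresholds()
    fit: FitOptions = FitOptions()
    #: flip the global sign convention of both response components
    sign_flip: bool = False
    #: quadrature nodes of the lognormal moment average in forward runs
    n_nodes: int = 25

    def __post_init__(self):
        if self.n_nodes < 21:
            raise ConfigError("n_nodes must be at least 21")


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid '{name}' section: {err}") from None


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {"thresholds", "fit", "sign_flip", "n_nodes"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    thresholds = _build(HysteresisThresholds, raw.get("thresholds", {}), "thresholds")
    fit = _build(FitOptions, raw.get("fit", {}), "fit")
    return RunConfig(
        thresholds=thresholds,
        fit=fit,
        sign_flip=bool(raw.get("sign_flip", False)),
        n_nodes=int(raw.get("n_nodes", 25)),
    )
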