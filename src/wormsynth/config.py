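"""Run configuration: YAML loading with strict key validation and seeding.

A run is fully described by (config, seed): every random stream in the
package is derived deterministically from the root seed, and the seed is
recorded in every output manifest.  Unknown configuration keys are rejected
by name rather than silently ignored — misspelled parameters in a generation
config would otherwise silently change the study conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .detector import DetectorParams
from .pipeline import GenerationConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


def _build(cls, data: dict[str, Any], path: str):
    """Instantiate a (frozen) dataclass from a dict, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} in section '{path}'; "
            f"known keys: {sorted(known)}"
        )
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
            value = _build(f.type, value, f"{path}.{name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section '{path}': {exc}") from None


@dataclass(frozen=True)
class RunConfig:
    """Root configuration for all subcommands."""

    seed: int = 0
    out: str = "wormsynth-out"
    n_images: int = 50
    generate: GenerationConfig = field(default_factory=GenerationConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    iou_threshold: float = 0.5
    seconds_per_worm: float = 5.0


def load_config(path: str | Path | None, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a YAML run config, apply flat overrides, validate strictly."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data = loaded
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    # resolve nested sections against their dataclass types
    for section, cls in (("generate", GenerationConfig), ("detector", DetectorParams)):
        if section in data and isinstance(data[section], dict):
            data[section] = _build(cls, data[section], section)
    return _build(RunConfig, data, "run")
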