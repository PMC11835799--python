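"""Run configuration: TOML/YAML parsing and validation.

A config file holds up to four sections::

    [model]       # ModelParams fields (coupling constants, constriction, ...)
    [scenario]    # ScenarioSpec fields (agents, groups, BPM, phase shift, ...)
    [simulation]  # duration, dt, seed, divergence_bound
    [measures]    # sigma, downsample, per_group

Unknown sections or keys are rejected.  Angle-valued scenario keys may be
given in degrees by using the ``_deg`` suffix (e.g. ``phase_shift_deg``); a
``phase_shift_rad`` key is converted to degrees on load.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model_core import ModelParams
from .synthetic_data import ScenarioSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class SimulationSettings:
    duration: float = 60.0
    dt: float = 1.0 / 120.0
    seed: Optional[int] = None
    divergence_bound: float = 1e3


@dataclass
class MeasureSettings:
    sigma: float = 1.0
    downsample: int = 1
    per_group: bool = True


@dataclass
class RunConfig:
    """Validated bundle of model, scenario, integration and measure settings."""

    model: ModelParams = field(default_factory=ModelParams)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    measures: MeasureSettings = field(default_factory=MeasureSettings)


_SECTION_TYPES = {
    "model": ModelParams,
    "scenario": ScenarioSpec,
    "simulation": SimulationSettings,
    "measures": MeasureSettings,
}


def _coerce_section(name: str, cls, raw: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    converted = {}
    for key, value in raw.items():
        if key == "phase_shift_rad" and "phase_shift_deg" in allowed:
            converted["phase_shift_deg"] = float(np.rad2deg(value))
            continue
        if key not in allowed:
            raise ValueError(f"unknown key '{key}' in config section [{name}]")
        converted[key] = value
    return cls(**converted)


def load_config(path) -> RunConfig:
    """Load and validate a TOML (.toml) or YAML (.yml/.yaml) run config."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    elif suffix in (".yml", ".yaml"):
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raise ValueError(f"unsupported config format '{suffix}' (use .toml or .yaml)")
    if not isinstance(raw, dict):
        raise ValueError("config root must be a table/mapping")
    unknown = set(raw) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section [{name}] must be a table/mapping")
        kwargs[name] = _coerce_section(name, cls, section)
    return RunConfig(**kwargs)
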