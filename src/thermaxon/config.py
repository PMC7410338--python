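"""Run configuration: YAML round trip, validation, reproducibility metadata.

A :class:`RunConfig` pins everything a full run depends on — geometry,
membrane, gate kinetics, sweep grid, solver settings, robustness criterion,
synthetic-generator parameters and the master seed — so a run is reproducible
from its config plus the package version alone.  Output files written by the
pipeline embed the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .kinetics import GateKinetics
from .membrane import AxonSpec, ChannelSet, MembraneSpec
from .phase import GeneratorParams, SigmoidFit, CyclePeriodModel
from .solver import SolverSettings, StimulusSpec
from .sweep import SweepGrid
from .timing import RobustnessCriterion

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config", "save_config"]


def _plain(obj):
    """Recursively convert tuples and numpy scalars to plain YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (bool, int, str)) or obj is None:
        return obj
    if isinstance(obj, float):
        return float(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproduction run depends on."""

    axon: AxonSpec = AxonSpec()
    membrane: MembraneSpec = MembraneSpec()
    channels: ChannelSet = ChannelSet()
    solver: SolverSettings = SolverSettings()
    stimulus: StimulusSpec = StimulusSpec()
    grid: SweepGrid = SweepGrid()
    robustness: RobustnessCriterion = RobustnessCriterion()
    generator: GeneratorParams = GeneratorParams()
    periods: CyclePeriodModel = CyclePeriodModel()
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["grid"]["fixed_properties"] = dict(self.grid.fixed_properties)
        gen = d["generator"]
        gen["fits"] = {k: asdict(v) for k, v in self.generator.fits.items()}
        gen["v5_m_per_s"] = dict(self.generator.v5_m_per_s)
        d["robustness"]["absolute_thresholds"] = dict(
            self.robustness.absolute_thresholds
        )
        return _plain(d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTIONS = {
    "axon": AxonSpec,
    "membrane": MembraneSpec,
    "solver": SolverSettings,
    "stimulus": StimulusSpec,
    "grid": SweepGrid,
    "robustness": RobustnessCriterion,
    "periods": CyclePeriodModel,
}


def _build_channels(data: Mapping[str, Any]) -> ChannelSet:
    kwargs = {name: GateKinetics(**gate) for name, gate in data.items()}
    return ChannelSet(**kwargs)


def _build_generator(data: Mapping[str, Any]) -> GeneratorParams:
    data = dict(data)
    if "fits" in data:
        data["fits"] = {k: SigmoidFit(**v) for k, v in data["fits"].items()}
    if "temperatures" in data:
        data["temperatures"] = tuple(data["temperatures"])
    return GeneratorParams(**data)


def validate_config(data: Mapping[str, Any] | RunConfig) -> list[str]:
    """Check a raw config mapping; returns all errors, not just the first."""
    if isinstance(data, RunConfig):
        return []
    errors: list[str] = []
    known = set(_SECTIONS) | {"channels", "generator", "seed"}
    for key in data:
        if key not in known:
            errors.append(f"unknown section {key!r}; allowed: {sorted(known)}")
    for key, cls in _SECTIONS.items():
        if key not in data:
            continue
        section = data[key]
        if not isinstance(section, Mapping):
            errors.append(f"section {key!r} must be a mapping")
            continue
        try:
            if key == "grid" and "fixed_properties" not in section:
                cls(**section)
            elif key == "grid":
                sec = dict(section)
                for tup in ("q10_values", "varied_properties", "diameters_um", "temperatures"):
                    if tup in sec:
                        sec[tup] = tuple(sec[tup])
                cls(**sec)
            else:
                cls(**section)
        except (TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
    for key, builder in (("channels", _build_channels), ("generator", _build_generator)):
        if key in data:
            try:
                builder(data[key])
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
    if "seed" in data and not isinstance(data["seed"], int):
        errors.append("seed must be an integer")
    return errors


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    errors = validate_config(data)
    if errors:
        raise ConfigError(errors)
    kwargs: dict[str, Any] = {}
    for key, cls in _SECTIONS.items():
        if key in data:
            sec = dict(data[key])
            if key == "grid":
                for tup in ("q10_values", "varied_properties", "diameters_um", "temperatures"):
                    if tup in sec:
                        sec[tup] = tuple(sec[tup])
            kwargs[key] = cls(**sec)
    if "channels" in data:
        kwargs["channels"] = _build_channels(data["channels"])
    if "generator" in data:
        kwargs["generator"] = _build_generator(data["generator"])
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config file into a validated :class:`RunConfig`."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(["config file must contain a mapping"])
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` restores an equal object."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )
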