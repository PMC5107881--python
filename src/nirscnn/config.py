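"""Run configuration: YAML/JSON loading with strict validation.

A :class:`RunConfig` bundles every stage's parameters.  Loading an empty
file yields the full default setup (learning rate 0.05, momentum 0.998,
1 x 10 kernels, 1 x 2 pooling, 9 kernels, 5000 epochs, 22-subject
24-channel cohort at 10 Hz); unknown keys and invalid values are rejected
with errors naming the offending field.  The single global seed is
propagated deterministically to the simulator, the per-fold classifier
initializations and the final interpretation model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .cnn import CNNConfig
from .preprocess import PreprocessParams
from .synth import NoiseSpec, SimulationConfig, TaskSchedule

__all__ = ["RunConfig", "load_config", "save_config", "derive_stage_seeds"]


@dataclass(frozen=True)
class RunConfig:
    """Nested configuration of the full simulate->preprocess->roi->interpret run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    roi_strategy: str = "topk"
    roi_param: float = 5
    interpret_neuron: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.roi_strategy not in ("topk", "threshold"):
            raise ValueError("roi_strategy must be 'topk' or 'threshold'")
        if self.roi_strategy == "topk" and int(self.roi_param) <= 0:
            raise ValueError("roi_param (k) must be positive")
        if self.roi_strategy == "threshold" and not 0 <= self.roi_param <= 1:
            raise ValueError("roi_param (threshold) must lie in [0, 1]")
        if self.interpret_neuron not in (0, 1):
            raise ValueError("interpret_neuron must be 0 or 1")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage seeds (< 2**31) derived from the global seed."""
    names = ("simulation", "loocv", "final_model")
    states = np.random.SeedSequence(int(seed)).generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, states)}


def _build(cls, mapping: dict, context: str):
    """Construct a dataclass from a mapping, rejecting unknown keys and
    re-raising constructor errors with the field path."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: {exc}") from exc


_NESTED_SIM = {"schedule": TaskSchedule, "noise": NoiseSpec}


def _build_simulation(mapping: dict) -> SimulationConfig:
    mapping = dict(mapping or {})
    for key, cls in _NESTED_SIM.items():
        if key in mapping and isinstance(mapping[key], dict):
            mapping[key] = _build(cls, mapping[key], f"simulation.{key}")
    if "discriminative_channels" in mapping:
        mapping["discriminative_channels"] = frozenset(
            mapping["discriminative_channels"])
    if "effect_window" in mapping:
        mapping["effect_window"] = tuple(mapping["effect_window"])
    if "noise" in mapping and not isinstance(mapping["noise"], (dict, NoiseSpec)):
        raise ValueError("simulation.noise: expected a mapping")
    return _build(SimulationConfig, mapping, "simulation")


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[dict[str, Any]] = None) -> RunConfig:
    """Load a YAML (or JSON) run configuration.

    ``None`` or an empty file gives the full defaults.  ``overrides`` is
    a top-level update applied after reading (used by CLI flags).
    """
    doc: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ValueError(f"config file not found: {p}")
        try:
            loaded = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config file {p}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {p} must contain a mapping")
            doc = loaded
    if overrides:
        doc = {**doc, **{k: v for k, v in overrides.items() if v is not None}}

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")

    sim = doc.get("simulation")
    sim = sim if isinstance(sim, SimulationConfig) else _build_simulation(sim or {})
    pre = doc.get("preprocess")
    pre = pre if isinstance(pre, PreprocessParams) else _build(
        PreprocessParams, pre or {}, "preprocess")
    cnn = doc.get("cnn")
    cnn = cnn if isinstance(cnn, CNNConfig) else _build(CNNConfig, cnn or {}, "cnn")
    top = {k: doc[k] for k in doc if k not in ("simulation", "preprocess", "cnn")}
    return _build(
        RunConfig,
        {"simulation": sim, "preprocess": pre, "cnn": cnn, **top},
        "run config",
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Write the configuration as YAML; ``load_config`` round-trips it."""
    path = Path(path)
    path.write_text(yaml.safe_dump(_jsonable(config), sort_keys=True))
    return path
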