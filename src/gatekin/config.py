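"""Declarative run configuration.

A RunConfig mirrors the parameter blocks of the library modules (grid,
landscape, motion, solver, gating, protocol) plus a global seed and unit
system.  It round-trips losslessly through YAML/JSON and rejects unknown
keys, so a stored config reproduces a run exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .gating import GatingParams
from .grids import ConfigGrid
from .landscape import LandscapeParams, PenaltyWalls, Well
from .motion import MotionParams
from .prob_evolution import SolverConfig

__all__ = ["GridSpec", "RunConfig", "load_config", "save_config", "named_rngs"]


def named_rngs(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Split one run seed into independent named streams (collision,
    trajectory, fixture, ...) so modules never share or reuse draws."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass(frozen=True)
class GridSpec:
    z_min: float = -14.0
    z_max: float = 6.0
    z_step: float = 0.2
    phi_min: float = -1.0
    phi_max: float = 1.0
    phi_step: float = 0.05

    def build(self) -> ConfigGrid:
        nz = int(round((self.z_max - self.z_min) / self.z_step)) + 1
        np_ = int(round((self.phi_max - self.phi_min) / self.phi_step)) + 1
        return ConfigGrid(
            z_values=np.round(self.z_min + self.z_step * np.arange(nz), 10),
            phi_values=np.round(self.phi_min + self.phi_step * np.arange(np_), 10),
        )


@dataclass(frozen=True)
class RunConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    motion: MotionParams = field(default_factory=MotionParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    gating: GatingParams = field(default_factory=GatingParams)
    protocol: tuple[dict, ...] = (
        {"vm_mV": -40.0, "duration_ms": 150.0},
        {"vm_mV": -20.0, "duration_ms": 150.0},
        {"vm_mV": 0.0, "duration_ms": 150.0},
        {"vm_mV": 20.0, "duration_ms": 150.0},
        {"vm_mV": 40.0, "duration_ms": 150.0},
        {"vm_mV": 60.0, "duration_ms": 150.0},
    )
    holding_vm: float = -100.0
    seed: int = 0
    units: str = "reduced"

    def __post_init__(self) -> None:
        if self.units not in ("reduced", "SI"):
            raise ValueError("units must be 'reduced' or 'SI'")

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in config section '{path}'")
    return cls(**data)


def _from_dict(data: dict) -> RunConfig:
    data = dict(data)
    kwargs: dict = {}
    if "grid" in data:
        kwargs["grid"] = _build(GridSpec, data.pop("grid"), "grid")
    if "landscape" in data:
        ls = dict(data.pop("landscape"))
        if "wells" in ls:
            ls["wells"] = tuple(
                Well(
                    center=tuple(w["center"]),
                    depth=w["depth"],
                    widths=tuple(w["widths"]),
                )
                for w in ls["wells"]
            )
        if "penalty" in ls:
            ls["penalty"] = _build(PenaltyWalls, dict(ls["penalty"]), "landscape.penalty")
        kwargs["landscape"] = _build(LandscapeParams, ls, "landscape")
    if "motion" in data:
        mo = dict(data.pop("motion"))
        if "omega" in mo:
            mo["omega"] = tuple(tuple(row) for row in mo["omega"])
        kwargs["motion"] = _build(MotionParams, mo, "motion")
    if "solver" in data:
        so = dict(data.pop("solver"))
        if "omega" in so:
            so["omega"] = tuple(tuple(row) for row in so["omega"])
        if isinstance(so.get("c1"), list):
            so["c1"] = tuple(so["c1"])
        kwargs["solver"] = _build(SolverConfig, so, "solver")
    if "gating" in data:
        kwargs["gating"] = _build(GatingParams, data.pop("gating"), "gating")
    if "protocol" in data:
        kwargs["protocol"] = tuple(dict(s) for s in data.pop("protocol"))
    for key in ("holding_vm", "seed", "units"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ValueError(f"unknown top-level config keys {sorted(data)}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    # guard: the written file must reproduce the config exactly
    if load_config(Path(path)) != config:
        raise RuntimeError("config did not round-trip losslessly")
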