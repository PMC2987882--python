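"""Plain-text run configurations (YAML) and their validation.

A configuration selects a built-in model by name, an initial density, one
task and its task-specific blocks.  Parsing is strict: unknown keys and
missing required blocks raise :class:`ConfigError` naming the offending
field path, and a parsed configuration round-trips through
``to_dict``/``from_dict`` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .characteristics import SolverSettings
from .densities import (
    ExponentialDensity,
    InitialDensity,
    NormalDensity,
    ProductDensity,
    UniformBoxDensity,
)
from .errors import ConfigError
from .grids import NodeGrid, UniformGrid
from .likelihood import ObservationSet
from .models import get_model
from .vectorfields import ParametricModel, bind_parameters, extend_with_parameters

TASKS = (
    "propagate",
    "region-mass",
    "marginal",
    "likelihood",
    "profile",
    "mc-compare",
)

__all__ = [
    "RunConfig",
    "TASKS",
    "load_config",
    "save_config",
    "build_density",
    "build_grid",
    "build_node_grid",
    "build_settings",
    "build_observations",
]


@dataclass
class RunConfig:
    task: str
    model: dict
    initial_density: dict
    time: float | None = None
    times: list | None = None
    region: dict | None = None
    keep_axes: list | None = None
    initial_points: dict | None = None
    data: dict | None = None
    param_grid: dict | None = None
    profiled: list | None = None
    extended_by: list | None = None
    n_samples: int | None = None
    settings: dict | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        if not isinstance(raw, Mapping):
            raise ConfigError("<root>", "configuration must be a mapping")
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration key")
        for req in ("task", "model", "initial_density"):
            if req not in raw:
                raise ConfigError(req, "required key is missing")
        cfg = cls(**{k: raw[k] for k in raw})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = {}
        for f in _dc_fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        return out

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        if self.task not in TASKS:
            raise ConfigError("task", f"must be one of {TASKS}, got {self.task!r}")
        if not isinstance(self.model, Mapping) or "name" not in self.model:
            raise ConfigError("model.name", "model block must name a model")
        get_model(self.model["name"])  # raises on unknown names
        params = self.model.get("params", {})
        if not isinstance(params, Mapping):
            raise ConfigError("model.params", "must be a mapping of name -> value")
        if self.task in ("propagate",):
            if self.times is None:
                raise ConfigError("times", "propagate requires output times")
            if self.initial_points is None:
                raise ConfigError(
                    "initial_points", "propagate requires an initial point set"
                )
        if self.task in ("region-mass", "marginal", "mc-compare"):
            if self.region is None:
                raise ConfigError("region", f"{self.task} requires a grid block")
            if self.time is None:
                raise ConfigError("time", f"{self.task} requires a final time")
        if self.task == "marginal" and not self.keep_axes:
            raise ConfigError("keep_axes", "marginal requires kept axis indices")
        if self.task in ("likelihood", "profile"):
            if self.data is None:
                raise ConfigError("data", f"{self.task} requires a data block")
        if self.task == "profile":
            if not self.profiled:
                raise ConfigError("profiled", "profile requires parameter names")
            if self.param_grid is None:
                raise ConfigError("param_grid", "profile requires a grid block")
        if self.task == "mc-compare":
            if not self.n_samples or self.n_samples < 1:
                raise ConfigError("n_samples", "mc-compare requires n_samples >= 1")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# -- block builders -----------------------------------------------------------

def build_model(config: RunConfig) -> tuple[ParametricModel, dict]:
    model = get_model(config.model["name"])
    params = {k: float(v) for k, v in config.model.get("params", {}).items()}
    return model, params


def build_bound_field(config: RunConfig):
    """Vector field for the configured model: bound to its parameter values,
    or extended by the parameters listed under ``extended_by`` (which then
    become trailing state coordinates with zero derivative)."""
    model, params = build_model(config)
    if config.extended_by:
        profiled = [str(p) for p in config.extended_by]
        fixed = {k: v for k, v in params.items() if k not in profiled}
        try:
            return extend_with_parameters(model, profiled, fixed)
        except ValueError as exc:
            raise ConfigError("extended_by", str(exc)) from exc
    merged = dict(model.defaults or {})
    merged.update(params)
    return bind_parameters(model, **merged)


def _density_from_block(block: Mapping, path: str) -> InitialDensity:
    if "kind" not in block:
        raise ConfigError(f"{path}.kind", "density block must declare a kind")
    kind = block["kind"]
    try:
        if kind == "normal":
            cov = block.get("cov", block.get("cov_diag", block.get("var")))
            if cov is None:
                raise ConfigError(
                    f"{path}", "normal density needs var, cov_diag or cov"
                )
            return NormalDensity(block["mean"], cov)
        if kind == "exponential":
            return ExponentialDensity(block["mean"])
        if kind == "uniform":
            return UniformBoxDensity(block["lo"], block["hi"])
    except ConfigError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(path, str(exc)) from exc
    raise ConfigError(f"{path}.kind", f"unknown density kind {kind!r}")


def build_density(block: Mapping, path: str = "initial_density") -> InitialDensity:
    if "components" in block:
        comps = block["components"]
        if not isinstance(comps, list) or not comps:
            raise ConfigError(f"{path}.components", "must be a non-empty list")
        parts = [
            _density_from_block(c, f"{path}.components[{i}]")
            for i, c in enumerate(comps)
        ]
        return parts[0] if len(parts) == 1 else ProductDensity(parts)
    return _density_from_block(block, path)


def _axes_from_block(block: Mapping, path: str) -> list[tuple[float, float, float]]:
    axes = block.get("axes")
    if not isinstance(axes, list) or not axes:
        raise ConfigError(f"{path}.axes", "must be a non-empty list of axes")
    out = []
    for i, ax in enumerate(axes):
        if isinstance(ax, Mapping):
            try:
                out.append((float(ax["lo"]), float(ax["hi"]), float(ax["h"])))
            except (KeyError, TypeError, ValueError):
                raise ConfigError(
                    f"{path}.axes[{i}]", "axis needs numeric lo, hi, h"
                ) from None
        else:
            try:
                lo, hi, h = ax
                out.append((float(lo), float(hi), float(h)))
            except (TypeError, ValueError):
                raise ConfigError(
                    f"{path}.axes[{i}]", "axis must be a (lo, hi, h) triple"
                ) from None
    return out


def build_grid(block: Mapping, path: str = "region") -> UniformGrid:
    try:
        return UniformGrid(_axes_from_block(block, path))
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from exc


def build_node_grid(block: Mapping, path: str = "param_grid") -> NodeGrid:
    try:
        return NodeGrid(_axes_from_block(block, path))
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from exc


def build_settings(block: Mapping | None) -> SolverSettings:
    if not block:
        return SolverSettings()
    try:
        return SolverSettings(**{k: block[k] for k in block})
    except (TypeError, ValueError) as exc:
        raise ConfigError("settings", str(exc)) from exc


def build_observations(block: Mapping, path: str = "data") -> ObservationSet:
    if "csv" in block:
        frame = pd.read_csv(block["csv"])
        if "time" not in frame.columns or frame.shape[1] < 2:
            raise ConfigError(
                f"{path}.csv", "CSV must have a 'time' column plus value columns"
            )
        times = frame["time"].to_numpy(dtype=float)
        if times.size == 0:
            raise ConfigError(f"{path}.csv", "CSV contains no data rows")
        if not np.all(times == times[0]):
            raise ConfigError(
                f"{path}.csv",
                "all rows must share one observation time (single-T contract)",
            )
        points = frame.drop(columns="time").to_numpy(dtype=float)
        return ObservationSet(float(times[0]), points)
    try:
        time = float(block["time"])
        points = np.asarray(block["points"], dtype=float)
    except (KeyError, TypeError, ValueError):
        raise ConfigError(path, "data block needs 'time' and 'points'") from None
    if points.size == 0:
        raise ConfigError(f"{path}.points", "at least one data point is required")
    try:
        return ObservationSet(time, points)
    except ValueError as exc:
        raise ConfigError(path, str(exc)) from exc
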