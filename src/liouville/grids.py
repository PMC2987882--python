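"""Uniform grids, midpoint-rule quadrature, marginals and region masses.

Two grid kinds are deliberately distinct:

* :class:`UniformGrid` -- cell-centered quadrature grids.  Centers sit at
  lo + h/2, lo + 3h/2, ..., strictly inside [lo, hi], so densities that are
  singular on a boundary (uniform box edges, the exponential at 0) are
  always evaluable, and the midpoint rule applies directly.
* :class:`NodeGrid` -- node-inclusive grids (lo, lo+h, ..., hi) used for
  likelihood profiles and initial discretizations, never for quadrature.

Quadrature is only meaningful on density fields produced by the
backward-forward procedure at a common final time (the values then live
exactly on the grid); forward-propagated point clouds are scattered and
carry no grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as _dfield
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import CapabilityError, SolverError

Array = np.ndarray

__all__ = [
    "UniformGrid",
    "NodeGrid",
    "DensityField",
    "build_uniform_grid",
    "midpoint_integrate",
    "marginalize",
    "density_on_grid",
    "region_mass",
]


def _validate_axis(i: int, lo: float, hi: float, h: float) -> int:
    if not (np.isfinite(lo) and np.isfinite(hi) and np.isfinite(h)):
        raise ValueError(f"axis {i}: bounds and step must be finite")
    if hi <= lo:
        raise ValueError(f"axis {i}: hi ({hi}) must exceed lo ({lo})")
    if h <= 0:
        raise ValueError(f"axis {i}: step h must be positive, got {h}")
    n = int(round((hi - lo) / h))
    if n < 1 or abs(n * h - (hi - lo)) > 1e-9 * max(1.0, abs(hi - lo)):
        raise ValueError(
            f"axis {i}: interval length {hi - lo} is not an integer multiple "
            f"of h={h}"
        )
    return n


class _GridBase:
    """Shared machinery: axes are (lo, hi, h) triples; the flattened point
    set is the row-major Cartesian product over axes in declaration order
    (fixed so CSV outputs are bit-for-bit reproducible)."""

    def __init__(self, axes: Sequence[tuple[float, float, float]]):
        self.axes = [tuple(float(v) for v in ax) for ax in axes]
        if not self.axes:
            raise ValueError("at least one axis required")
        self._n = [
            _validate_axis(i, lo, hi, h) for i, (lo, hi, h) in enumerate(self.axes)
        ]
        self._points: Array | None = None

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def steps(self) -> Array:
        return np.array([h for (_, _, h) in self.axes])

    def points(self) -> Array:
        if self._points is None:
            mesh = np.meshgrid(
                *[self.axis_values(i) for i in range(self.ndim)], indexing="ij"
            )
            self._points = np.stack([m.ravel() for m in mesh], axis=1)
        return self._points

    def axis_values(self, i: int) -> Array:  # pragma: no cover - abstract
        raise NotImplementedError


class UniformGrid(_GridBase):
    """Cell-centered uniform grid for midpoint-rule quadrature."""

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self._n)

    @property
    def n_points(self) -> int:
        return int(np.prod(self._n))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.steps))

    def axis_values(self, i: int) -> Array:
        lo, _, h = self.axes[i]
        return lo + h * (np.arange(self._n[i]) + 0.5)

    centers = axis_values

    def subgrid(self, keep_axes: Sequence[int]) -> "UniformGrid":
        return UniformGrid([self.axes[i] for i in keep_axes])


class NodeGrid(_GridBase):
    """Node-inclusive uniform grid: values lo, lo+h, ..., hi per axis."""

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(n + 1 for n in self._n)

    @property
    def n_points(self) -> int:
        return int(np.prod([n + 1 for n in self._n]))

    def axis_values(self, i: int) -> Array:
        lo, hi, h = self.axes[i]
        v = lo + h * np.arange(self._n[i] + 1)
        v[-1] = hi  # exact endpoint
        return v


def build_uniform_grid(axes: Sequence[tuple[float, float, float]]) -> UniformGrid:
    """Build a cell-centered grid from (lo, hi, h) triples."""
    return UniformGrid(axes)


@dataclass
class DensityField:
    """Density values attached to a set of points at a common time.

    When ``grid`` is present the points are exactly the grid's cell centers
    (row-major order) and the field supports midpoint-rule quadrature.
    ``status`` (one short string per point: "ok", "zero_density",
    "domain_exit", "failed") records per-point outcomes of batch solves.
    ``estimate`` marks Monte Carlo histogram estimates, which carry
    per-cell standard errors in ``stderr``.
    """

    time: float
    points: Array
    log_values: Array
    grid: UniformGrid | None = None
    status: np.ndarray | None = None
    estimate: bool = False
    stderr: Array | None = None
    meta: dict = _dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.log_values = np.asarray(self.log_values, dtype=float)
        if self.log_values.shape != (self.points.shape[0],):
            raise ValueError("log_values must have one entry per point")
        if self.grid is not None and self.points.shape[0] != self.grid.n_points:
            raise ValueError("points do not match the attached grid")

    @property
    def values(self) -> Array:
        with np.errstate(under="ignore"):
            return np.exp(self.log_values)

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def to_frame(self) -> pd.DataFrame:
        data = {f"x{i}": self.points[:, i] for i in range(self.dim)}
        data["log_density"] = self.log_values
        data["density"] = self.values
        if self.status is not None:
            data["status"] = self.status
        if self.stderr is not None:
            data["stderr"] = self.stderr
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def midpoint_integrate(field: DensityField) -> float:
    """Midpoint-rule integral: sum of cell-center values times cell volume."""
    if field.grid is None:
        raise CapabilityError(
            "midpoint quadrature requires a field attached to a uniform grid"
        )
    lse = logsumexp(field.log_values)
    if np.isneginf(lse):
        return 0.0
    return float(np.exp(lse + np.log(field.grid.cell_volume)))


def marginalize(field: DensityField, keep_axes: Sequence[int]) -> DensityField:
    """Integrate out the axes not in ``keep_axes`` by the midpoint rule.

    Summation associativity makes integrating the marginal over the kept
    axes exactly equal to integrating the original field over all axes.
    """
    if field.grid is None:
        raise CapabilityError("marginalization requires a grid-attached field")
    keep = sorted(set(int(a) for a in keep_axes))
    if not keep:
        raise ValueError("keep_axes must not be empty")
    if any(a < 0 or a >= field.grid.ndim for a in keep):
        raise ValueError(f"keep_axes out of range for a {field.grid.ndim}-d grid")
    if len(keep) >= field.grid.ndim:
        raise ValueError("keep_axes must be a strict subset of the grid axes")

    drop = tuple(a for a in range(field.grid.ndim) if a not in keep)
    log_cube = field.log_values.reshape(field.grid.shape)
    log_h_drop = float(np.sum(np.log([field.grid.axes[a][2] for a in drop])))
    marg = logsumexp(log_cube, axis=drop) + log_h_drop
    sub = field.grid.subgrid(keep)
    return DensityField(
        time=field.time,
        points=sub.points(),
        log_values=marg.ravel(),
        grid=sub,
        meta={**field.meta, "marginalized_from": field.grid.ndim, "kept_axes": keep},
    )


def density_on_grid(field_vec, u0, grid: UniformGrid, T: float, settings=None) -> DensityField:
    """Backward-forward density evaluated on a quadrature grid's cell
    centers at time T, returned with the grid attached."""
    from .characteristics import density_at_points  # local import: avoids cycle

    df = density_at_points(field_vec, u0, grid.points(), T, settings)
    return DensityField(
        time=df.time,
        points=df.points,
        log_values=df.log_values,
        grid=grid,
        status=df.status,
        meta=df.meta,
    )


def region_mass(
    field_vec,
    u0,
    region: UniformGrid,
    T: float,
    settings=None,
    max_fail_fraction: float = 0.01,
) -> float:
    """Probability mass of ``region`` at time T via backward-forward
    characteristics and midpoint quadrature."""
    df = density_on_grid(field_vec, u0, region, T, settings)
    if df.status is not None:
        failed = int(np.sum(df.status == "failed"))
        if failed > max_fail_fraction * region.n_points:
            raise SolverError(
                f"{failed}/{region.n_points} grid points failed to solve; "
                "region mass would be unreliable"
            )
    return midpoint_integrate(df)
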