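"""Likelihood of an ODE model for observed data, and grid profiling.

For data D = {xi_1(T), ..., xi_N(T)} observed at time T, the model
likelihood is the product of the output density at the data points,

    L = prod_i u(T, xi_i(T)),

evaluated point-by-point with the backward-forward procedure and summed in
log space (raw products of N densities underflow quickly).  Parameter
estimation profiles the log-likelihood over a node-inclusive grid of the
parameter of interest: for each grid value v the state is extended by the
parameter, the query (xi(T), v) is mapped backward to (xi(0), v), the joint
prior is evaluated there, and the extended system is integrated forward.
No continuous optimization is attempted; the estimate is the best grid
value (with an optional refinement pass around it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dfield
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .characteristics import SolverSettings, density_at_points
from .densities import InitialDensity
from .errors import DimensionError, EstimationError, FlatProfileWarning
from .grids import NodeGrid
from .vectorfields import ParametricModel, VectorField, extend_with_parameters

Array = np.ndarray

__all__ = [
    "ObservationSet",
    "LikelihoodResult",
    "LikelihoodProfile",
    "likelihood_of_data",
    "profile_parameter",
    "mle_from_profile",
]


@dataclass
class ObservationSet:
    """Data points observed at a common time T (full-state observations)."""

    time: float
    points: Array

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 0:
            pts = pts.reshape(1, 1)
        elif pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ValueError("points must be a non-empty (N, d) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all observed points must be finite")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class LikelihoodResult:
    """Per-point output densities and the total log-likelihood."""

    log_point_densities: Array
    log_likelihood: float

    @property
    def point_densities(self) -> Array:
        with np.errstate(under="ignore"):
            return np.exp(self.log_point_densities)


def likelihood_of_data(
    field: VectorField,
    u0: InitialDensity,
    obs: ObservationSet,
    settings: SolverSettings | None = None,
) -> LikelihoodResult:
    """Log-likelihood of the data under the output density u(T, .).

    A zero-density data point makes the total -inf; a *failed* solve makes
    the total undefined and raises :class:`EstimationError`."""
    if obs.points.shape[1] != field.dim:
        raise DimensionError(
            f"observation dimension {obs.points.shape[1]} != field dimension "
            f"{field.dim} (only full-state observations are supported)"
        )
    df = density_at_points(field, u0, obs.points, obs.time, settings)
    if df.status is not None and np.any(df.status == "failed"):
        bad = np.flatnonzero(df.status == "failed")
        raise EstimationError(
            f"solver failed for data point(s) {bad.tolist()}; "
            "likelihood is undefined"
        )
    total = float(np.sum(df.log_values))
    return LikelihoodResult(df.log_values, total)


@dataclass
class LikelihoodProfile:
    """Per-grid-value log-likelihoods with the tie-broken maximizer.

    ``ok`` flags grid values whose solves all succeeded; failed entries are
    NaN and skipped by the maximization.  Ties are broken toward the
    smallest parameter value (lexicographically for several parameters).
    """

    param_names: list[str]
    parameter_values: Array  # (K, q)
    log_likelihoods: Array  # (K,)
    ok: Array  # (K,) bool
    maximizer: Array | None = None
    gap: float | None = None
    meta: dict = _dfield(default_factory=dict)

    def __post_init__(self) -> None:
        if self.maximizer is None:
            self.maximizer, self.gap = mle_from_profile(self)

    @property
    def maximizer_scalar(self) -> float:
        """The maximizer as a float (single profiled parameter only)."""
        m = np.atleast_1d(self.maximizer)
        if m.size != 1:
            raise ValueError("profile has more than one profiled parameter")
        return float(m[0])

    def to_frame(self) -> pd.DataFrame:
        data = {
            name: self.parameter_values[:, j]
            for j, name in enumerate(self.param_names)
        }
        data["log_likelihood"] = self.log_likelihoods
        data["ok"] = self.ok
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            "Likelihood profile",
            "------------------",
            f"profiled parameter(s): {', '.join(self.param_names)}",
            f"grid values:           {self.parameter_values.shape[0]}",
            f"finite log-likelihoods: {int(np.sum(np.isfinite(self.log_likelihoods)))}",
            f"maximizer:             {np.atleast_1d(self.maximizer)}",
            f"gap to runner-up:      {self.gap:.6g}" if self.gap is not None else "",
        ]
        return "\n".join(line for line in lines if line)


def mle_from_profile(profile: LikelihoodProfile) -> tuple[Array, float | None]:
    """Tie-broken argmax of the profile plus the log-likelihood gap to the
    runner-up grid point.  Raises if no entry is finite."""
    ll = profile.log_likelihoods
    finite = np.isfinite(ll) & profile.ok
    if not np.any(finite):
        raise EstimationError(
            "no finite log-likelihood in the profile; cannot estimate"
        )
    vals = profile.parameter_values
    # ascending lexicographic order of the parameter values for tie-breaking
    order = np.lexsort(vals.T[::-1])
    best = -np.inf
    best_i = None
    for i in order:
        if finite[i] and ll[i] > best:
            best = ll[i]
            best_i = i
    others = finite.copy()
    others[best_i] = False
    gap = float(best - np.max(ll[others])) if np.any(others) else 0.0
    finite_vals = ll[finite]
    if finite_vals.size > 1 and np.allclose(
        finite_vals, finite_vals[0], rtol=0.0, atol=1e-12
    ):
        warnings.warn(
            "likelihood profile is flat; the maximizer is only a "
            "tie-breaking convention (smallest grid value)",
            FlatProfileWarning,
            stacklevel=2,
        )
    return vals[best_i].copy(), gap


def profile_parameter(
    model: ParametricModel,
    u0_joint: InitialDensity,
    obs: ObservationSet,
    param_grid: NodeGrid | Array,
    profiled: Sequence[str],
    fixed: Mapping[str, float] | None = None,
    settings: SolverSettings | None = None,
    refine: bool = False,
) -> LikelihoodProfile:
    """Profile the log-likelihood over a grid of parameter values.

    Parameters
    ----------
    u0_joint : InitialDensity
        Joint prior on (state, profiled parameters), coordinates ordered as
        state first, then the profiled parameters in the given order.
    param_grid : NodeGrid or (K,) / (K, q) array
        Node-inclusive grid of profiled-parameter values.
    refine : bool
        When True, one refinement pass re-grids around the maximizer at a
        quarter of the original spacing (off by default; the plain grid
        profile is the primary procedure).
    """
    profiled = list(profiled)
    if isinstance(param_grid, NodeGrid):
        values = param_grid.points()
    else:
        values = np.asarray(param_grid, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
    if values.shape[1] != len(profiled):
        raise DimensionError(
            f"grid has {values.shape[1]} parameter column(s), "
            f"expected {len(profiled)}"
        )
    ext = extend_with_parameters(model, profiled, fixed)
    if u0_joint.dim != ext.dim:
        raise DimensionError(
            f"joint prior dimension {u0_joint.dim} != extended dimension "
            f"{ext.dim} (state {model.state_dim} + {len(profiled)} profiled)"
        )
    if obs.points.shape[1] != model.state_dim:
        raise DimensionError(
            f"observations have dimension {obs.points.shape[1]}, "
            f"expected state dimension {model.state_dim}"
        )

    K = values.shape[0]
    ll = np.full(K, np.nan)
    ok = np.zeros(K, dtype=bool)
    for i in range(K):
        queries = np.hstack(
            [obs.points, np.tile(values[i], (obs.n, 1))]
        )
        df = density_at_points(ext, u0_joint, queries, obs.time, settings)
        if df.status is not None and np.any(df.status == "failed"):
            continue
        ll[i] = float(np.sum(df.log_values))
        ok[i] = True

    prof = LikelihoodProfile(
        param_names=profiled,
        parameter_values=values,
        log_likelihoods=ll,
        ok=ok,
        meta={"n_data": obs.n, "time": obs.time},
    )
    if refine and len(profiled) == 1 and isinstance(param_grid, NodeGrid):
        lo, hi, h = param_grid.axes[0]
        c = prof.maximizer_scalar
        h2 = h / 4.0
        lo2, hi2 = max(lo, c - h), min(hi, c + h)
        n2 = max(1, int(round((hi2 - lo2) / h2)))
        fine = np.linspace(lo2, lo2 + n2 * h2, n2 + 1)
        fine = fine[fine <= hi + 1e-12]
        return profile_parameter(
            model, u0_joint, obs, fine, profiled, fixed, settings, refine=False
        )
    return prof
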