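"""Autonomous ODE vector fields, their divergence, and parameter extension.

The central object is :class:`VectorField`, an autonomous right-hand side
``F`` on R^d together with an optional analytic divergence

    div F(x) = sum_i dF_i/dx_i  (the trace of the Jacobian of F),

which is the local exponential rate at which probability density changes
along trajectories.  Parametric models (state dynamics ``f(z|p)`` with
constant parameters ``p``) are represented by :class:`ParametricModel` and
turned into plain vector fields on the joint state-parameter space by
:func:`extend_with_parameters`: the parameters evolve with zero derivative,
so parameter uncertainty becomes initial-condition uncertainty.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field as _field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import DimensionError, DomainError, NumericalError

Array = np.ndarray

__all__ = [
    "VectorField",
    "ParametricModel",
    "evaluate_rhs",
    "divergence",
    "divergence_batch",
    "finite_difference_divergence",
    "extend_with_parameters",
    "bind_parameters",
]


def _as_point(x, dim: int) -> Array:
    x = np.asarray(x, dtype=float)
    if x.ndim == 0 and dim == 1:
        x = x.reshape(1)
    if x.shape != (dim,):
        raise DimensionError(
            f"expected a point of dimension {dim}, got shape {x.shape}"
        )
    return x


def _as_bound(b, dim: int, default: float) -> Array:
    if b is None:
        return np.full(dim, default)
    b = np.asarray(b, dtype=float)
    if b.shape != (dim,):
        raise DimensionError(f"bound must have length {dim}, got shape {b.shape}")
    return b


def _reject_time_dependent(fn: Callable, what: str) -> None:
    """Reject right-hand sides written as f(t, x): the density ODE is
    derived for autonomous systems only."""
    try:
        sig = inspect.signature(fn)
    except (TypeError, ValueError):  # builtins, ufuncs
        return
    required = [
        p
        for p in sig.parameters.values()
        if p.default is inspect.Parameter.empty
        and p.kind
        in (
            inspect.Parameter.POSITIONAL_ONLY,
            inspect.Parameter.POSITIONAL_OR_KEYWORD,
        )
    ]
    if len(required) > 1:
        raise ValueError(
            f"{what} must be autonomous: expected a single argument f(x), "
            f"got {len(required)} required positional arguments"
        )


@dataclass
class VectorField:
    """An autonomous vector field F : R^dim -> R^dim.

    Parameters
    ----------
    dim : int
        State dimension d.
    rhs : callable
        ``rhs(x) -> (d,)`` derivative at a single point.
    divergence : callable, optional
        Analytic ``div F(x) -> float``.  When absent, a central
        finite-difference trace of the Jacobian is used.
    domain_lo, domain_hi : array-like, optional
        Per-coordinate bounds of the region where ``rhs`` is meaningful
        (e.g. non-negative concentrations).  Unbounded by default.
    rhs_batch, divergence_batch : callable, optional
        Vectorized variants mapping an ``(N, d)`` array of points to an
        ``(N, d)`` array / length-``N`` vector.  When present, batch
        operations integrate all points as one stacked ODE system.
    """

    dim: int
    rhs: Callable[[Array], Array]
    divergence: Callable[[Array], float] | None = None
    domain_lo: Sequence[float] | None = None
    domain_hi: Sequence[float] | None = None
    rhs_batch: Callable[[Array], Array] | None = None
    divergence_batch: Callable[[Array], Array] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.dim, (int, np.integer)) or self.dim < 1:
            raise ValueError(f"dim must be a positive integer, got {self.dim!r}")
        self.dim = int(self.dim)
        _reject_time_dependent(self.rhs, "rhs")
        if self.divergence is not None:
            _reject_time_dependent(self.divergence, "divergence")
        if self.domain_lo is not None:
            self.domain_lo = _as_bound(self.domain_lo, self.dim, -np.inf)
        if self.domain_hi is not None:
            self.domain_hi = _as_bound(self.domain_hi, self.dim, np.inf)

    # -- convenience wrappers -------------------------------------------------
    def __call__(self, x) -> Array:
        return evaluate_rhs(self, x)

    def in_domain(self, x, atol: float = 1e-12) -> bool:
        x = np.asarray(x, dtype=float)
        if self.domain_lo is not None and np.any(x < self.domain_lo - atol):
            return False
        if self.domain_hi is not None and np.any(x > self.domain_hi + atol):
            return False
        return True


def _check_domain(field: VectorField, x: Array) -> None:
    if field.domain_lo is not None:
        below = np.nonzero(x < field.domain_lo - 1e-12)[0]
        if below.size:
            i = int(below[0])
            raise DomainError(
                f"coordinate {i} = {x[i]} is below the lower domain bound "
                f"{field.domain_lo[i]}"
            )
    if field.domain_hi is not None:
        above = np.nonzero(x > field.domain_hi + 1e-12)[0]
        if above.size:
            i = int(above[0])
            raise DomainError(
                f"coordinate {i} = {x[i]} is above the upper domain bound "
                f"{field.domain_hi[i]}"
            )


def evaluate_rhs(field: VectorField, x) -> Array:
    """Evaluate F(x), validating dimension and domain."""
    x = _as_point(x, field.dim)
    _check_domain(field, x)
    f = np.asarray(field.rhs(x), dtype=float)
    if f.shape != (field.dim,):
        raise DimensionError(
            f"rhs returned shape {f.shape}, expected ({field.dim},)"
        )
    return f


def finite_difference_divergence(field: VectorField, x: Array) -> float:
    """Central-difference trace of the Jacobian of F at x.

    Step per coordinate: h_i = sqrt(machine eps) * max(1, |x_i|).
    """
    x = np.asarray(x, dtype=float)
    h = np.sqrt(np.finfo(float).eps) * np.maximum(1.0, np.abs(x))
    total = 0.0
    for i in range(field.dim):
        e = np.zeros(field.dim)
        e[i] = h[i]
        fp = np.asarray(field.rhs(x + e), dtype=float)[i]
        fm = np.asarray(field.rhs(x - e), dtype=float)[i]
        total += (fp - fm) / (2.0 * h[i])
    return float(total)


def divergence(field: VectorField, x) -> float:
    """div F(x): analytic when supplied, otherwise finite differences."""
    x = _as_point(x, field.dim)
    _check_domain(field, x)
    if field.divergence is not None:
        d = float(field.divergence(x))
    else:
        d = finite_difference_divergence(field, x)
    if not np.isfinite(d):
        raise NumericalError(f"divergence is non-finite at x={x}: {d}")
    return d


def divergence_batch(field: VectorField, X: Array) -> Array:
    """Vectorized divergence over an (N, d) array of points.

    Uses the field's analytic batch divergence when present, a batched
    central difference built on ``rhs_batch`` otherwise, and a plain
    per-row loop as a last resort.  No domain validation (internal use by
    the characteristic solver, which records domain exits separately).
    """
    X = np.asarray(X, dtype=float)
    if field.divergence_batch is not None:
        return np.asarray(field.divergence_batch(X), dtype=float)
    if field.rhs_batch is not None:
        h = np.sqrt(np.finfo(float).eps) * np.maximum(1.0, np.abs(X))
        out = np.zeros(X.shape[0])
        for i in range(field.dim):
            E = np.zeros_like(X)
            E[:, i] = h[:, i]
            fp = np.asarray(field.rhs_batch(X + E), dtype=float)[:, i]
            fm = np.asarray(field.rhs_batch(X - E), dtype=float)[:, i]
            out += (fp - fm) / (2.0 * h[:, i])
        return out
    if field.divergence is not None:
        return np.array([float(field.divergence(row)) for row in X])
    return np.array([finite_difference_divergence(field, row) for row in X])


@dataclass
class ParametricModel:
    """State dynamics f(z|p) with n state variables and m constant parameters.

    ``defaults`` carries the reference parameter values; ``div_state`` is the
    divergence of f with respect to the state z alone (the parameters, having
    zero derivative, contribute nothing to the divergence of the extended
    field).
    """

    state_dim: int
    param_dim: int
    rhs_given_params: Callable[[Array, Array], Array]
    param_names: Sequence[str]
    div_state: Callable[[Array, Array], float] | None = None
    rhs_batch_given_params: Callable[[Array, Array], Array] | None = None
    div_state_batch: Callable[[Array, Array], Array] | None = None
    domain_lo: Sequence[float] | None = None
    domain_hi: Sequence[float] | None = None
    defaults: Mapping[str, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.state_dim < 1:
            raise ValueError("state_dim must be positive")
        if self.param_dim < 0:
            raise ValueError("param_dim must be non-negative")
        self.param_names = list(self.param_names)
        if len(self.param_names) != self.param_dim:
            raise ValueError(
                f"expected {self.param_dim} parameter names, "
                f"got {len(self.param_names)}"
            )

    def param_vector(self, values: Mapping[str, float]) -> Array:
        """Assemble a parameter vector in declaration order from a mapping,
        filling gaps from ``defaults``."""
        merged = dict(self.defaults or {})
        unknown = set(values) - set(self.param_names)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        merged.update(values)
        missing = [n for n in self.param_names if n not in merged]
        if missing:
            raise ValueError(f"missing parameter values for: {missing}")
        return np.array([float(merged[n]) for n in self.param_names])


def bind_parameters(model: ParametricModel, **params: float) -> VectorField:
    """Fix all parameters, yielding a vector field on the state space alone."""
    p = model.param_vector(params)

    def rhs(z: Array) -> Array:
        return np.asarray(model.rhs_given_params(z, p), dtype=float)

    div = None
    if model.div_state is not None:
        def div(z: Array, _p: Array = p) -> float:  # noqa: E731-style closure
            return float(model.div_state(z, _p))

    rhs_b = None
    if model.rhs_batch_given_params is not None:
        def rhs_b(Z: Array, _p: Array = p) -> Array:
            P = np.broadcast_to(_p, (Z.shape[0], p.size))
            return np.asarray(model.rhs_batch_given_params(Z, P), dtype=float)

    div_b = None
    if model.div_state_batch is not None:
        def div_b(Z: Array, _p: Array = p) -> Array:
            P = np.broadcast_to(_p, (Z.shape[0], p.size))
            return np.asarray(model.div_state_batch(Z, P), dtype=float)

    return VectorField(
        dim=model.state_dim,
        rhs=rhs,
        divergence=div,
        domain_lo=model.domain_lo,
        domain_hi=model.domain_hi,
        rhs_batch=rhs_b,
        divergence_batch=div_b,
        name=model.name,
    )


def extend_with_parameters(
    model: ParametricModel,
    profiled: Sequence[str] | None = None,
    fixed: Mapping[str, float] | None = None,
) -> VectorField:
    """Extend the state space by (a subset of) the parameters.

    The returned field has dimension ``n + k`` where ``k`` is the number of
    profiled parameters: its rhs stacks ``f(z|p)`` over the first n
    coordinates and zeros over the parameter coordinates, and its divergence
    is the state divergence of ``f`` alone.

    Parameters
    ----------
    profiled : sequence of parameter names, optional
        Parameters appended to the state (in the given order).  Defaults to
        all parameters in declaration order.
    fixed : mapping, optional
        Values for the remaining parameters (merged over ``defaults``).
    """
    if profiled is None:
        profiled = list(model.param_names)
    profiled = list(profiled)
    unknown = [q for q in profiled if q not in model.param_names]
    if unknown:
        raise ValueError(f"unknown profiled parameters: {unknown}")
    if len(set(profiled)) != len(profiled):
        raise ValueError("profiled parameter names must be distinct")

    n, m, k = model.state_dim, model.param_dim, len(profiled)
    prof_idx = np.array(
        [model.param_names.index(q) for q in profiled], dtype=int
    )
    merged = dict(model.defaults or {})
    merged.update(fixed or {})
    template = np.zeros(m)
    for j, nm in enumerate(model.param_names):
        if j in prof_idx:
            continue
        if nm not in merged:
            raise ValueError(f"no value for non-profiled parameter {nm!r}")
        template[j] = float(merged[nm])

    def assemble(x: Array) -> tuple[Array, Array]:
        p = template.copy()
        p[prof_idx] = x[n:]
        return x[:n], p

    def rhs(x: Array) -> Array:
        z, p = assemble(x)
        out = np.zeros(n + k)
        out[:n] = model.rhs_given_params(z, p)
        return out

    div = None
    if model.div_state is not None:
        def div(x: Array) -> float:
            z, p = assemble(x)
            return float(model.div_state(z, p))

    rhs_b = None
    div_b = None
    if model.rhs_batch_given_params is not None:
        def _assemble_batch(X: Array) -> tuple[Array, Array]:
            N = X.shape[0]
            P = np.tile(template, (N, 1))
            P[:, prof_idx] = X[:, n:]
            return X[:, :n], P

        def rhs_b(X: Array) -> Array:
            Z, P = _assemble_batch(X)
            out = np.zeros((X.shape[0], n + k))
            out[:, :n] = model.rhs_batch_given_params(Z, P)
            return out

        if model.div_state_batch is not None:
            def div_b(X: Array) -> Array:
                Z, P = _assemble_batch(X)
                return np.asarray(model.div_state_batch(Z, P), dtype=float)

    lo = hi = None
    if model.domain_lo is not None:
        lo = np.concatenate([np.asarray(model.domain_lo, float), np.full(k, -np.inf)])
    if model.domain_hi is not None:
        hi = np.concatenate([np.asarray(model.domain_hi, float), np.full(k, np.inf)])

    suffix = f" + ({', '.join(profiled)})" if k else ""
    return VectorField(
        dim=n + k,
        rhs=rhs,
        divergence=div,
        domain_lo=lo,
        domain_hi=hi,
        rhs_batch=rhs_b,
        divergence_batch=div_b,
        name=model.name + suffix,
    )
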