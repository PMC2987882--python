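"""Initial probability densities u0 on the (extended) state space.

Densities are handled in log space throughout the package: the tails
studied by the characteristic solver span many orders of magnitude and
would underflow in linear space.  Every density exposes

* ``log_density(x)``  -- log u0(x), -inf outside the support,
* ``log_density_batch(X)`` -- vectorized over an (N, d) array,
* ``sample(n, seed)`` -- reproducible draws (where supported).

Built-ins: multivariate normal (scalar/diagonal/full covariance),
exponential on the open half-line, uniform box (closed; its boundary is
excluded from quadrature by the cell-centered grid construction), and
arbitrary products of these.  User densities are accepted through
:class:`CallableDensity`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .errors import CapabilityError, DimensionError

Array = np.ndarray

__all__ = [
    "InitialDensity",
    "NormalDensity",
    "ExponentialDensity",
    "UniformBoxDensity",
    "ProductDensity",
    "CallableDensity",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class InitialDensity:
    """Base class: a probability density on R^dim with optional support box."""

    dim: int
    support_lo: Array | None = None
    support_hi: Array | None = None

    def _check_point(self, x) -> Array:
        x = np.asarray(x, dtype=float)
        if x.ndim == 0 and self.dim == 1:
            x = x.reshape(1)
        if x.shape != (self.dim,):
            raise DimensionError(
                f"expected a point of dimension {self.dim}, got shape {x.shape}"
            )
        return x

    def _check_points(self, X) -> Array:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1 and self.dim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != self.dim:
            raise DimensionError(
                f"expected points of shape (N, {self.dim}), got {X.shape}"
            )
        return X

    def log_density(self, x) -> float:
        raise NotImplementedError

    def log_density_batch(self, X) -> Array:
        X = self._check_points(X)
        return np.array([self.log_density(row) for row in X])

    def sample(self, n: int, seed: int) -> Array:
        raise CapabilityError(
            f"{type(self).__name__} does not support sampling"
        )


def _validate_count(n: int) -> int:
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    return int(n)


class NormalDensity(InitialDensity):
    """Multivariate normal N(mean, cov); cov may be a scalar variance,
    a vector of per-coordinate variances, or a full covariance matrix."""

    def __init__(self, mean, cov):
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        self.dim = mean.size
        self.mean = mean
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 0:
            cov = np.eye(self.dim) * float(cov)
        elif cov.ndim == 1:
            if cov.size != self.dim:
                raise DimensionError("diagonal covariance length mismatch")
            cov = np.diag(cov)
        if cov.shape != (self.dim, self.dim):
            raise DimensionError(
                f"covariance shape {cov.shape} incompatible with dim {self.dim}"
            )
        self.cov = cov
        self._chol = np.linalg.cholesky(cov)
        self._log_det = 2.0 * np.sum(np.log(np.diag(self._chol)))

    def log_density(self, x) -> float:
        x = self._check_point(x)
        y = np.linalg.solve(self._chol, x - self.mean)
        return float(-0.5 * (self.dim * _LOG_2PI + self._log_det + y @ y))

    def log_density_batch(self, X) -> Array:
        X = self._check_points(X)
        Y = np.linalg.solve(self._chol, (X - self.mean).T)
        return -0.5 * (self.dim * _LOG_2PI + self._log_det + np.sum(Y * Y, axis=0))

    def sample(self, n: int, seed: int) -> Array:
        n = _validate_count(n)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.dim))
        return self.mean + z @ self._chol.T


class ExponentialDensity(InitialDensity):
    """Exponential distribution with the given mean, supported on x > 0."""

    def __init__(self, mean: float):
        mean = float(mean)
        if mean <= 0:
            raise ValueError(f"mean must be positive, got {mean}")
        self.dim = 1
        self.mean = mean
        self.support_lo = np.array([0.0])
        self._log_rate = -np.log(mean)

    def log_density(self, x) -> float:
        x = self._check_point(x)
        if x[0] <= 0.0:
            return -np.inf
        return float(self._log_rate - x[0] / self.mean)

    def log_density_batch(self, X) -> Array:
        X = self._check_points(X)
        x = X[:, 0]
        out = np.where(x > 0.0, self._log_rate - x / self.mean, -np.inf)
        return out

    def sample(self, n: int, seed: int) -> Array:
        n = _validate_count(n)
        rng = np.random.default_rng(seed)
        return rng.exponential(self.mean, size=(n, 1))


class UniformBoxDensity(InitialDensity):
    """Uniform density on the closed box [lo, hi] (constant 1/volume inside,
    including the boundary; zero outside)."""

    def __init__(self, lo, hi):
        lo = np.atleast_1d(np.asarray(lo, dtype=float))
        hi = np.atleast_1d(np.asarray(hi, dtype=float))
        if lo.shape != hi.shape:
            raise DimensionError("lo and hi must have the same length")
        if np.any(hi <= lo):
            raise ValueError("each hi must exceed the corresponding lo")
        self.dim = lo.size
        self.lo, self.hi = lo, hi
        self.support_lo, self.support_hi = lo, hi
        self._log_value = -float(np.sum(np.log(hi - lo)))

    def log_density(self, x) -> float:
        x = self._check_point(x)
        if np.all(x >= self.lo) and np.all(x <= self.hi):
            return self._log_value
        return -np.inf

    def log_density_batch(self, X) -> Array:
        X = self._check_points(X)
        inside = np.all((X >= self.lo) & (X <= self.hi), axis=1)
        return np.where(inside, self._log_value, -np.inf)

    def sample(self, n: int, seed: int) -> Array:
        n = _validate_count(n)
        rng = np.random.default_rng(seed)
        return rng.uniform(self.lo, self.hi, size=(n, self.dim))


class ProductDensity(InitialDensity):
    """Independent product of component densities over consecutive
    coordinate blocks; its log-density is the sum of component values."""

    def __init__(self, components: Sequence[InitialDensity]):
        if not components:
            raise ValueError("at least one component required")
        self.components = list(components)
        self.dim = sum(c.dim for c in self.components)
        splits = np.cumsum([c.dim for c in self.components])[:-1]
        self._splits = splits
        los, his = [], []
        for c in self.components:
            los.append(
                c.support_lo if c.support_lo is not None else np.full(c.dim, -np.inf)
            )
            his.append(
                c.support_hi if c.support_hi is not None else np.full(c.dim, np.inf)
            )
        lo = np.concatenate(los)
        hi = np.concatenate(his)
        self.support_lo = lo if np.any(np.isfinite(lo)) else None
        self.support_hi = hi if np.any(np.isfinite(hi)) else None

    def log_density(self, x) -> float:
        x = self._check_point(x)
        parts = np.split(x, self._splits)
        return float(
            sum(c.log_density(part) for c, part in zip(self.components, parts))
        )

    def log_density_batch(self, X) -> Array:
        X = self._check_points(X)
        out = np.zeros(X.shape[0])
        start = 0
        for c in self.components:
            out += c.log_density_batch(X[:, start : start + c.dim])
            start += c.dim
        return out

    def sample(self, n: int, seed: int) -> Array:
        n = _validate_count(n)
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(len(self.components))]
        blocks = [
            c.sample(n, s) for c, s in zip(self.components, child_seeds)
        ]
        return np.concatenate(blocks, axis=1)


class CallableDensity(InitialDensity):
    """A user-defined density given by a log-density callable with a
    declared support box and an optional sampler ``(n, seed) -> (n, dim)``."""

    def __init__(
        self,
        dim: int,
        log_density_fn: Callable[[Array], float],
        support_lo=None,
        support_hi=None,
        sampler: Callable[[int, int], Array] | None = None,
    ):
        if dim < 1:
            raise ValueError("dim must be positive")
        self.dim = int(dim)
        self._fn = log_density_fn
        self.support_lo = (
            None if support_lo is None else np.asarray(support_lo, dtype=float)
        )
        self.support_hi = (
            None if support_hi is None else np.asarray(support_hi, dtype=float)
        )
        self._sampler = sampler

    def log_density(self, x) -> float:
        x = self._check_point(x)
        if self.support_lo is not None and np.any(x < self.support_lo):
            return -np.inf
        if self.support_hi is not None and np.any(x > self.support_hi):
            return -np.inf
        return float(self._fn(x))

    def sample(self, n: int, seed: int) -> Array:
        if self._sampler is None:
            raise CapabilityError(
                "this density was defined without a sampler"
            )
        n = _validate_count(n)
        pts = np.asarray(self._sampler(n, seed), dtype=float)
        if pts.shape != (n, self.dim):
            raise DimensionError(
                f"sampler returned shape {pts.shape}, expected ({n}, {self.dim})"
            )
        return pts
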