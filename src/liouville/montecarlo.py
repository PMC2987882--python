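"""Monte Carlo reference: ensemble propagation and histogram density.

This is the conventional sampling alternative the characteristic solver is
compared against: (i) sample the initial density, (ii) integrate each
sample forward, (iii) estimate the density by relative frequency on grid
cells, u(T, x) ~ #{xi_i(T) in cell}/N / volume.  Only the plain histogram
estimator is offered -- kernel methods need problem-specific bandwidth
choices, and the oracle must stay assumption-free.  The per-cell standard
error sqrt(p(1-p)/N)/volume quantifies the sampling noise that makes
low-probability regions expensive for Monte Carlo: covering a region
holding 0.1% of the mass with ~100 points requires ~100,000 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .characteristics import SolverSettings, _batch_states, _solve
from .densities import InitialDensity
from .errors import SolverError
from .grids import DensityField, UniformGrid
from .vectorfields import VectorField

Array = np.ndarray

__all__ = ["EnsembleResult", "monte_carlo_ensemble", "histogram_density"]

DEFAULT_MC_SETTINGS = SolverSettings(rel_tol=1e-8, abs_tol=1e-10)


@dataclass
class EnsembleResult:
    """Time-T images of iid draws from the initial density."""

    time: float
    points: Array  # (n - n_failed, d)
    seed: int
    n: int
    n_failed: int = 0


def monte_carlo_ensemble(
    field: VectorField,
    u0: InitialDensity,
    n: int,
    T: float,
    seed: int,
    settings: SolverSettings | None = None,
    chunk_size: int = 25_000,
) -> EnsembleResult:
    """Sample u0 and integrate every sample forward to time T.

    A single seed governs the sampling; integration is deterministic, so the
    result is reproducible from (seed, n, settings).  Per-sample solver
    failures are excluded from the ensemble, with a warning when more than
    0.1% fail."""
    settings = settings or DEFAULT_MC_SETTINGS
    samples = u0.sample(n, seed)
    if T < 0:
        raise ValueError(f"T must be non-negative, got {T}")
    if T == 0:
        return EnsembleResult(0.0, samples, seed, n, 0)

    t_out = np.array([0.0, float(T)])
    blocks: list[Array] = []
    n_failed = 0
    for start in range(0, n, chunk_size):
        chunk = samples[start : start + chunk_size]
        propagated = None
        if field.rhs_batch is not None:
            try:
                propagated = _batch_states(field, chunk, t_out, settings)[-1]
            except SolverError:
                propagated = None
        if propagated is None:
            rows = []
            for x0 in chunk:
                try:
                    def fun(_t, y):
                        return np.asarray(field.rhs(y), dtype=float)

                    rows.append(_solve(fun, x0, t_out, settings).y[:, -1])
                except SolverError:
                    n_failed += 1
            propagated = (
                np.array(rows) if rows else np.empty((0, field.dim))
            )
        finite = np.all(np.isfinite(propagated), axis=1)
        n_failed += int(np.sum(~finite))
        blocks.append(propagated[finite])

    points = np.concatenate(blocks, axis=0) if blocks else np.empty((0, field.dim))
    if n_failed > 0.001 * n:
        warnings.warn(
            f"{n_failed}/{n} Monte Carlo trajectories failed and were excluded",
            stacklevel=2,
        )
    return EnsembleResult(float(T), points, seed, n, n_failed)


def histogram_density(ensemble: EnsembleResult, grid: UniformGrid) -> DensityField:
    """Relative-frequency density estimate on the grid's cells.

    Per cell: count/(N * cell volume) with N the total sample count, and
    standard error sqrt(p(1-p)/N)/volume.  Points outside the grid are
    counted into an overflow total reported in ``meta``.  The result is
    flagged as an estimate (``estimate=True``); it is not a quadrature-grade
    density field."""
    edges = [
        np.concatenate([[lo], lo + h * (np.arange(nc) + 1.0)])
        for (lo, hi, h), nc in zip(grid.axes, grid.shape)
    ]
    counts, _ = np.histogramdd(ensemble.points, bins=edges)
    counts = counts.ravel()
    n_inside = int(counts.sum())
    overflow = ensemble.points.shape[0] - n_inside

    N = ensemble.n - ensemble.n_failed
    vol = grid.cell_volume
    p_hat = counts / N
    with np.errstate(divide="ignore"):
        log_values = np.log(p_hat) - np.log(vol)
    stderr = np.sqrt(p_hat * (1.0 - p_hat) / N) / vol
    return DensityField(
        time=ensemble.time,
        points=grid.points(),
        log_values=log_values,
        grid=grid,
        estimate=True,
        stderr=stderr,
        meta={
            "n_samples": ensemble.n,
            "n_failed": ensemble.n_failed,
            "n_overflow": int(overflow),
            "seed": ensemble.seed,
        },
    )
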