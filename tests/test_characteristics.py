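"""The characteristic solver: extended ODE, backward map, backward-forward."""

import warnings

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import multivariate_normal, norm

import liouville as lv


class TestPropagatePair:
    def test_linear_decay_closed_form(self, linear_decay):
        # div F = -1, so log rho grows linearly at rate +1
        traj = lv.propagate_pair(linear_decay, [1.0], 0.0, [0.0, 1.0])
        assert traj.states[-1, 0] == pytest.approx(np.exp(-1.0), rel=1e-8)
        assert traj.log_rho[-1] == pytest.approx(1.0, abs=1e-8)

    def test_divergence_free_rotation_keeps_density_constant(self, planar_rotation):
        traj = lv.propagate_pair(
            planar_rotation, [1.0, 0.5], -2.3, np.linspace(0, 4.0, 9)
        )
        np.testing.assert_allclose(traj.log_rho, -2.3, atol=1e-8)

    def test_zero_density_short_circuits(self, linear_decay):
        traj = lv.propagate_pair(linear_decay, [1.0], -np.inf, [0.0, 1.0])
        assert np.all(np.isneginf(traj.log_rho))
        assert traj.states[-1, 0] == pytest.approx(np.exp(-1.0), rel=1e-8)

    def test_semigroup_property(self, autoreg, u0_autoreg):
        x0, lr0 = np.array([1.5]), u0_autoreg.log_density([1.5])
        one = lv.propagate_pair(autoreg, x0, lr0, [0.0, 13.0])
        two_a = lv.propagate_pair(autoreg, x0, lr0, [0.0, 5.0])
        two_b = lv.propagate_pair(
            autoreg, two_a.states[-1], two_a.log_rho[-1], [0.0, 8.0]
        )
        assert two_b.states[-1, 0] == pytest.approx(one.states[-1, 0], rel=1e-7)
        assert two_b.log_rho[-1] == pytest.approx(one.log_rho[-1], abs=1e-6)

    def test_invalid_time_grid_rejected(self, linear_decay):
        with pytest.raises(ValueError, match="start at 0"):
            lv.propagate_pair(linear_decay, [1.0], 0.0, [1.0, 2.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            lv.propagate_pair(linear_decay, [1.0], 0.0, [0.0, 2.0, 1.0])


class TestBackwardMap:
    def test_time_zero_is_identity(self, autoreg):
        x = np.array([5.0])
        assert lv.backward_map(autoreg, x, 0.0) == pytest.approx(x)

    def test_linear_decay_closed_form(self, linear_decay):
        x0 = lv.backward_map(linear_decay, [np.exp(-1.0)], 1.0)
        assert x0[0] == pytest.approx(1.0, rel=1e-8)

    def test_autoregulation_round_trip_from_observation(self, autoreg):
        x0 = lv.backward_map(autoreg, [5.0], 20.0)
        fwd = lv.propagate_pair(autoreg, x0, 0.0, [0.0, 20.0])
        assert fwd.states[-1, 0] == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize("model_T", [("autoreg", 50.0), ("toggle", 10.0)])
    def test_round_trip_on_bulk_points(self, model_T, request, u0_autoreg, u0_toggle):
        """Backward then forward recovers final-time bulk points to 1e-6."""
        name, T = model_T
        field = request.getfixturevalue(name)
        u0 = u0_autoreg if name == "autoreg" else u0_toggle
        starts = u0.sample(8, seed=4)
        trajs = lv.propagate_initial_grid(field, u0, starts, [0.0, T])
        with warnings.catch_warnings():
            warnings.simplefilter("error", lv.ConditioningWarning)
            for traj in trajs:
                xT = traj.states[-1]
                x0 = lv.backward_map(field, xT, T)  # check=True would warn
                fwd = lv.propagate_pair(field, x0, 0.0, [0.0, T])
                err = np.max(np.abs(fwd.states[-1] - xT) / np.maximum(1, np.abs(xT)))
                assert err < 1e-6


class TestDensityAtPoints:
    def test_time_zero_returns_initial_density(self, autoreg, u0_autoreg):
        pts = np.array([[1.0], [2.0], [3.5]])
        df = lv.density_at_points(autoreg, u0_autoreg, pts, 0.0)
        np.testing.assert_allclose(
            df.log_values, u0_autoreg.log_density_batch(pts)
        )

    def test_linear_decay_pushforward_closed_form(self, linear_decay):
        # dx/dt = -k x with u0 = N(0,1): u(t,x) = e^{kt} phi(x e^{kt}), k=1
        u0 = lv.NormalDensity([0.0], 1.0)
        t = 1.0
        xs = np.linspace(-1.0, 1.0, 11)[:, None]
        df = lv.density_at_points(linear_decay, u0, xs, t)
        expected = np.exp(t) * norm.pdf(xs[:, 0] * np.exp(t))
        np.testing.assert_allclose(df.values, expected, rtol=1e-7)

    def test_linear_2d_system_matches_normal_pushforward(self):
        """For dx/dt = A x with normal u0, the output density is the normal
        with mean e^{At} mu0 and covariance e^{At} S0 e^{A't}."""
        A = np.array([[0.3, -1.0], [0.8, -0.5]])
        field = lv.VectorField(
            2, lambda x: A @ x, divergence=lambda x: float(np.trace(A))
        )
        mu0, S0 = np.array([0.5, -0.2]), np.array([[0.4, 0.1], [0.1, 0.3]])
        u0 = lv.NormalDensity(mu0, S0)
        t = 1.0
        E = expm(A * t)
        mu_t, S_t = E @ mu0, E @ S0 @ E.T
        pts = np.random.default_rng(0).multivariate_normal(mu_t, S_t, size=50)
        df = lv.density_at_points(field, u0, pts, t)
        exact = multivariate_normal(mu_t, S_t).logpdf(pts)
        rel = np.abs(np.expm1(df.log_values - exact))
        assert np.max(rel) < 1e-6

    def test_zero_prior_preimage_reports_zero_density(self, linear_decay):
        u0 = lv.UniformBoxDensity([0.0], [1.0])
        # backward map of x=-1 lands at -e < 0, outside the support
        df = lv.density_at_points(linear_decay, u0, [[-1.0]], 1.0)
        assert df.values[0] == 0.0
        assert df.status[0] == "zero_density"

    def test_loop_and_batch_paths_agree(self, autoreg, u0_autoreg):
        pts = np.linspace(0.5, 9.5, 7)[:, None]
        batch = lv.density_at_points(autoreg, u0_autoreg, pts, 50.0)
        stripped = lv.VectorField(
            1, autoreg.rhs, divergence=autoreg.divergence, domain_lo=[0.0]
        )
        loop = lv.density_at_points(stripped, u0_autoreg, pts, 50.0)
        assert batch.meta["mode"] == "batch"
        assert loop.meta["mode"] == "loop"
        np.testing.assert_allclose(batch.log_values, loop.log_values, atol=1e-7)

    def test_per_point_failure_isolation(self):
        """One blow-up trajectory must not destroy the batch."""
        # dx/dt = -x^3 explodes backward in finite time from large |x|
        field = lv.VectorField(1, lambda x: -(x**3), divergence=lambda x: -3 * x[0] ** 2)
        u0 = lv.NormalDensity([0.0], 1.0)
        pts = np.array([[0.2], [40.0]])
        df = lv.density_at_points(field, u0, pts, 1.0)
        assert df.status[1] == "failed"
        assert df.status[0] == "ok"
        assert np.isfinite(df.log_values[0])


class TestForwardBackwardConsistency:
    def test_autoregulation_forward_grid_matches_targeted_queries(
        self, autoreg, u0_autoreg
    ):
        nodes = lv.NodeGrid([(0.0, 5.0, 0.05)]).points()
        assert nodes.shape == (101, 1)
        trajs = lv.propagate_initial_grid(autoreg, u0_autoreg, nodes, [0.0, 50.0])
        ends = np.array([t.states[-1] for t in trajs])
        fwd = np.array([t.log_rho[-1] for t in trajs])
        df = lv.density_at_points(autoreg, u0_autoreg, ends, 50.0)
        fin = np.isfinite(fwd)
        assert np.max(np.abs(df.log_values[fin] - fwd[fin])) < 1e-5

    def test_toggle_forward_grid_matches_targeted_queries(self, toggle, u0_toggle):
        """Consistency is checked at t=2: for longer horizons the density
        contracts onto the slow manifold and the backward pass becomes
        exponentially ill-conditioned transverse to it."""
        starts = u0_toggle.sample(20, seed=5)
        trajs = lv.propagate_initial_grid(toggle, u0_toggle, starts, [0.0, 2.0])
        ends = np.array([t.states[-1] for t in trajs])
        fwd = np.array([t.log_rho[-1] for t in trajs])
        df = lv.density_at_points(toggle, u0_toggle, ends, 2.0)
        assert np.max(np.abs(df.log_values - fwd)) < 1e-4

    def test_exponential_initial_density_conserves_mass(self, autoreg):
        """The method applies to non-normal priors: with x0 exponential of
        mean 2, the backward-forward density at t = 50 still integrates
        to 1 over a support-covering grid."""
        u0 = lv.ExponentialDensity(2.0)
        grid = lv.UniformGrid([(0.0, 70.0, 0.1)])
        df = lv.density_on_grid(autoreg, u0, grid, 50.0)
        assert lv.midpoint_integrate(df) == pytest.approx(1.0, abs=1e-3)

    def test_constant_field_keeps_density_constant(self):
        field = lv.VectorField(
            1,
            lambda x: np.array([0.7]),
            rhs_batch=lambda X: np.full_like(X, 0.7),
            divergence_batch=lambda X: np.zeros(X.shape[0]),
        )
        u0 = lv.NormalDensity([0.0], 1.0)
        trajs = lv.propagate_initial_grid(
            field, u0, np.linspace(-2, 2, 9)[:, None], np.linspace(0, 3, 7)
        )
        for traj in trajs:
            np.testing.assert_allclose(traj.log_rho, traj.log_rho[0], atol=1e-9)
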