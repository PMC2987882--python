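"""Likelihood of data and grid profiling of parameters."""

import numpy as np
import pytest

import liouville as lv
from liouville.likelihood import LikelihoodProfile


FIXED = {"K": 2.0, "k_d": 0.01, "beta": 4.0}


class TestLikelihoodOfData:
    def test_time_zero_single_datum_is_prior_height(self, linear_decay):
        u0 = lv.NormalDensity([0.0], 1.0)
        obs = lv.ObservationSet(0.0, [[0.0]])
        res = lv.likelihood_of_data(linear_decay, u0, obs)
        assert res.point_densities[0] == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_duplicated_datum_doubles_log_likelihood(self, autoreg, u0_autoreg):
        one = lv.likelihood_of_data(
            autoreg, u0_autoreg, lv.ObservationSet(20.0, [[5.0]])
        )
        two = lv.likelihood_of_data(
            autoreg, u0_autoreg, lv.ObservationSet(20.0, [[5.0], [5.0]])
        )
        assert two.log_likelihood == pytest.approx(2 * one.log_likelihood, rel=1e-9)

    def test_matches_density_at_points(self, autoreg, u0_autoreg):
        obs = lv.ObservationSet(20.0, [[5.0], [7.0], [12.0]])
        res = lv.likelihood_of_data(autoreg, u0_autoreg, obs)
        df = lv.density_at_points(autoreg, u0_autoreg, obs.points, 20.0)
        np.testing.assert_allclose(
            res.log_point_densities, df.log_values, rtol=1e-12
        )
        assert res.log_likelihood == pytest.approx(np.sum(df.log_values), rel=1e-12)

    def test_empty_or_nonfinite_observations_rejected(self):
        with pytest.raises(ValueError):
            lv.ObservationSet(1.0, np.empty((0, 1)))
        with pytest.raises(ValueError, match="finite"):
            lv.ObservationSet(1.0, [[np.nan]])


def _profile(values, lls):
    values = np.asarray(values, dtype=float)[:, None]
    lls = np.asarray(lls, dtype=float)
    return LikelihoodProfile(
        param_names=["theta"],
        parameter_values=values,
        log_likelihoods=lls,
        ok=np.isfinite(lls) | np.isneginf(lls),
    )


class TestMleFromProfile:
    def test_unique_maximum(self):
        p = _profile([0.5, 1.0, 1.5], [-3.0, -1.0, -2.0])
        assert p.maximizer_scalar == 1.0
        assert p.gap == pytest.approx(1.0)

    def test_tie_broken_toward_smallest_value(self):
        p = _profile([0.5, 1.0, 1.5], [-1.0, -2.0, -1.0])
        assert p.maximizer_scalar == 0.5
        assert p.gap == pytest.approx(0.0)

    def test_flat_profile_warns_and_returns_smallest(self):
        with pytest.warns(lv.FlatProfileWarning):
            p = _profile([0.2, 0.6, 1.0], [-1.0, -1.0, -1.0])
        assert p.maximizer_scalar == 0.2

    def test_all_minus_infinity_raises(self):
        with pytest.raises(lv.EstimationError):
            _profile([0.5, 1.0], [-np.inf, -np.inf])


@pytest.fixture(scope="module")
def model():
    return lv.get_model("autoregulation")


@pytest.fixture(scope="module")
def obs():
    return lv.ObservationSet(20.0, [[5.0]])


@pytest.fixture(scope="module")
def grid():
    return lv.NodeGrid([(0.0, 2.0, 0.05)])


class TestProfileParameter:
    def test_normal_prior_estimate_near_prior_mean(self, model, obs, grid):
        prior = lv.NormalDensity([2.0, 1.0], [0.2, 0.01])
        prof = lv.profile_parameter(model, prior, obs, grid, ["V_max"], fixed=FIXED)
        assert abs(prof.maximizer_scalar - 1.0) <= 0.05 + 1e-12
        assert "maximizer" in prof.summary()

    def test_flat_prior_estimate_driven_by_dynamics(self, model, obs, grid):
        prior = lv.ProductDensity(
            [lv.NormalDensity([2.0], 0.2), lv.UniformBoxDensity([0.0], [2.0])]
        )
        prof = lv.profile_parameter(model, prior, obs, grid, ["V_max"], fixed=FIXED)
        assert abs(prof.maximizer_scalar - 0.2) <= 0.05 + 1e-12

    def test_profile_value_matches_density_query(self, model, obs):
        """Each profile entry is the joint output density at (xi(T), v)."""
        v = 0.8
        prof = lv.profile_parameter(
            model,
            lv.NormalDensity([2.0, 1.0], [0.2, 0.01]),
            obs,
            np.array([v]),
            ["V_max"],
            fixed=FIXED,
        )
        ext = lv.extend_with_parameters(model, ["V_max"], FIXED)
        df = lv.density_at_points(
            ext, lv.NormalDensity([2.0, 1.0], [0.2, 0.01]), [[5.0, v]], 20.0
        )
        assert prof.log_likelihoods[0] == pytest.approx(df.log_values[0], rel=1e-12)

    def test_prior_dominance_as_parameter_variance_shrinks(self, model, obs, grid):
        """With an ever-tighter prior on V_max the estimate converges to the
        prior mean."""
        distances = []
        for var in (0.01, 0.001, 0.0001):
            prior = lv.NormalDensity([2.0, 1.0], [0.2, var])
            prof = lv.profile_parameter(model, prior, obs, grid, ["V_max"], fixed=FIXED)
            distances.append(abs(prof.maximizer_scalar - 1.0))
        assert distances[0] <= 0.05 + 1e-12
        assert distances == sorted(distances, reverse=True) or distances[-1] == 0.0
        assert distances[-1] == 0.0

    def test_parameter_not_entering_dynamics_gives_flat_profile(self, obs):
        model = lv.ParametricModel(
            state_dim=1,
            param_dim=2,
            rhs_given_params=lambda z, p: np.array([-p[0] * z[0]]),
            param_names=["k", "unused"],
            div_state=lambda z, p: -p[0],
            defaults={"k": 0.05, "unused": 1.0},
        )
        prior = lv.ProductDensity(
            [lv.NormalDensity([5.0], 0.5), lv.UniformBoxDensity([0.0], [2.0])]
        )
        grid = lv.NodeGrid([(0.0, 2.0, 0.5)])
        with pytest.warns(lv.FlatProfileWarning):
            prof = lv.profile_parameter(
                model, prior, lv.ObservationSet(1.0, [[4.0]]), grid, ["unused"]
            )
        assert prof.maximizer_scalar == 0.0

    def test_recovers_generating_parameter_from_synthetic_data(self, model, grid):
        """25 observations simulated at T=20 with true V_max=1 from the
        initial density: the flat-prior profile peaks within 0.1 of 1."""
        field = lv.build_autoregulation(V_max=1.0, **FIXED)
        u0 = lv.NormalDensity([2.0], 0.2)
        starts = u0.sample(25, seed=12345)
        trajs = lv.propagate_initial_grid(field, u0, starts, [0.0, 20.0])
        data = np.array([t.states[-1] for t in trajs])
        obs = lv.ObservationSet(20.0, data)
        prior = lv.ProductDensity([u0, lv.UniformBoxDensity([0.0], [2.0])])
        prof = lv.profile_parameter(model, prior, obs, grid, ["V_max"], fixed=FIXED)
        assert abs(prof.maximizer_scalar - 1.0) <= 0.1
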