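"""Vector fields, divergences and parameter extension."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import liouville as lv
from liouville.vectorfields import finite_difference_divergence


class TestEvaluateRhs:
    def test_autoregulation_reference_point(self, autoreg):
        # V_max*x^b/(K^b+x^b) - k_d*x = 16/32 - 0.02 at x=2
        assert lv.evaluate_rhs(autoreg, [2.0]) == pytest.approx([0.48])

    def test_toggle_reference_point(self, toggle):
        # 5/(1+9) - 3 per component at (3,3)
        assert lv.evaluate_rhs(toggle, [3.0, 3.0]) == pytest.approx([-2.5, -2.5])

    def test_zero_field_returns_zero_vector(self):
        zero = lv.VectorField(3, lambda x: np.zeros(3))
        assert np.all(lv.evaluate_rhs(zero, [1.0, -2.0, 0.5]) == 0.0)

    def test_dimension_mismatch_rejected(self, toggle):
        with pytest.raises(lv.DimensionError):
            lv.evaluate_rhs(toggle, [1.0, 2.0, 3.0])

    def test_domain_violation_names_coordinate(self, toggle):
        with pytest.raises(lv.DomainError, match="coordinate 1"):
            lv.evaluate_rhs(toggle, [1.0, -0.5])

    def test_time_dependent_rhs_rejected(self):
        with pytest.raises(ValueError, match="autonomous"):
            lv.VectorField(1, lambda t, x: -x)


class TestDivergence:
    def test_autoregulation_reference_point(self, autoreg):
        # d/dx of the Hill rhs at x=2: 512/1024 - 0.01
        assert lv.divergence(autoreg, [2.0]) == pytest.approx(0.49)

    def test_linear_decay_constant(self, linear_decay):
        for x in (-3.0, 0.0, 7.5):
            assert lv.divergence(linear_decay, [x]) == pytest.approx(-1.0)

    def test_rotation_divergence_free(self, planar_rotation):
        assert lv.divergence(planar_rotation, [1.3, -2.1]) == pytest.approx(0.0)

    def test_finite_difference_fallback_matches_analytic(self, autoreg):
        no_div = lv.VectorField(1, autoreg.rhs)
        for x in (0.5, 2.0, 8.0):
            assert lv.divergence(no_div, [x]) == pytest.approx(
                lv.divergence(autoreg, [x]), rel=1e-6
            )

    @pytest.mark.parametrize("name", ["autoregulation", "toggle_switch"])
    def test_analytic_agrees_with_jacobian_trace_at_random_points(self, name):
        field = lv.build_vector_field(name)
        rng = np.random.default_rng(2024)
        pts = rng.uniform(0.2, 8.0, size=(100, field.dim))
        for x in pts:
            fd = finite_difference_divergence(field, x)
            assert lv.divergence(field, x) == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_batch_divergence_matches_pointwise(self, toggle):
        X = np.array([[3.0, 3.0], [1.0, 0.5], [4.5, 0.2]])
        from liouville.vectorfields import divergence_batch

        batch = divergence_batch(toggle, X)
        point = [lv.divergence(toggle, x) for x in X]
        np.testing.assert_allclose(batch, point, rtol=1e-12)


class TestParameterExtension:
    def test_autoregulation_extended_by_vmax(self):
        model = lv.get_model("autoregulation")
        ext = lv.extend_with_parameters(model, ["V_max"])
        assert ext.dim == 2
        np.testing.assert_allclose(ext.rhs(np.array([2.0, 1.0])), [0.48, 0.0])
        assert lv.divergence(ext, [2.0, 1.0]) == pytest.approx(0.49)

    def test_full_extension_stacks_zeros(self):
        model = lv.get_model("toggle_switch")
        ext = lv.extend_with_parameters(model, ["alpha1", "alpha2"])
        x = np.array([3.0, 3.0, 5.0, 5.0])
        np.testing.assert_allclose(ext.rhs(x), [-2.5, -2.5, 0.0, 0.0])

    def test_no_parameters_behaves_like_bound_model(self):
        model = lv.get_model("autoregulation")
        ext = lv.extend_with_parameters(model, [])
        bound = lv.build_autoregulation()
        assert ext.dim == bound.dim
        for x in (0.5, 2.0, 6.0):
            assert ext.rhs(np.array([x])) == pytest.approx(bound.rhs(np.array([x])))

    def test_projection_recovers_state_dynamics(self):
        model = lv.get_model("autoregulation")
        ext = lv.extend_with_parameters(model)
        rng = np.random.default_rng(5)
        for _ in range(20):
            z = rng.uniform(0.1, 6.0, size=1)
            p = model.param_vector(
                {"V_max": rng.uniform(0.2, 2), "K": 2.0, "k_d": 0.01, "beta": 4.0}
            )
            full = ext.rhs(np.concatenate([z, p]))
            np.testing.assert_array_equal(full[:1], model.rhs_given_params(z, p))
            assert np.all(full[1:] == 0.0)

    def test_unknown_profiled_name_rejected(self):
        model = lv.get_model("autoregulation")
        with pytest.raises(ValueError, match="unknown profiled"):
            lv.extend_with_parameters(model, ["nope"])


class TestBuiltinModels:
    def test_autoregulation_saturates_for_large_x(self, autoreg):
        x = 1e6
        # Hill term ~ V_max, so rhs ~ V_max - k_d*x
        assert lv.evaluate_rhs(autoreg, [x])[0] == pytest.approx(
            1.0 - 0.01 * x, rel=1e-10
        )

    def test_autoregulation_at_origin(self, autoreg):
        assert lv.evaluate_rhs(autoreg, [0.0])[0] == 0.0
        assert lv.divergence(autoreg, [0.0]) == pytest.approx(-0.01)

    def test_toggle_symmetry(self, toggle):
        a, b = 1.7, 0.4
        f_ab = lv.evaluate_rhs(toggle, [a, b])
        f_ba = lv.evaluate_rhs(toggle, [b, a])
        np.testing.assert_allclose(f_ab, f_ba[::-1], rtol=1e-14)

    def test_toggle_equilibrium_residual(self, toggle):
        # stable fixed point with x1 high / x2 low, located independently
        root = fsolve(lambda z: toggle.rhs(z), x0=np.array([4.8, 0.2]), full_output=False)
        assert np.max(np.abs(toggle.rhs(root))) < 1e-9

    @pytest.mark.parametrize(
        "builder,bad",
        [
            (lv.build_autoregulation, {"V_max": -1.0}),
            (lv.build_autoregulation, {"k_d": 0.0}),
            (lv.build_toggle_switch, {"q1": -2.0}),
        ],
    )
    def test_non_positive_parameters_rejected(self, builder, bad):
        with pytest.raises(ValueError, match="positive"):
            builder(**bad)

    def test_registry_rejects_unknown_model(self):
        with pytest.raises(KeyError, match="unknown model"):
            lv.get_model("lorenz")
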