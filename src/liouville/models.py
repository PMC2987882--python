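"""Built-in gene-expression models.

Two classic gene-regulatory circuits are shipped:

``autoregulation``
    A protein X activating its own expression through cooperative promoter
    binding (a Hill activation term) and diluted by cell growth:

        dx/dt = V_max * x^beta / (K^beta + x^beta) - k_d * x

    with maximal expression rate V_max, half-activation concentration K,
    cooperativity beta and dilution rate constant k_d.

``toggle_switch``
    Two proteins mutually repressing each other's expression:

        dx1/dt = alpha1 / (1 + (x2/q1)^beta1) - k_d * x1
        dx2/dt = alpha2 / (1 + (x1/q2)^beta2) - k_d * x2

    with effective expression rates alpha_i, repression cooperativities
    beta_i, half-repression concentrations q_i and dilution rate k_d.

Both declare non-negative-orthant domains (concentrations) and carry
analytic divergences.  Units are conventional (concentrations in
mol/volume, rates per unit time) and are documentation only.
"""

from __future__ import annotations

import numpy as np

from .vectorfields import ParametricModel, VectorField, bind_parameters

__all__ = [
    "autoregulation_model",
    "toggle_switch_model",
    "build_autoregulation",
    "build_toggle_switch",
    "MODEL_REGISTRY",
    "get_model",
    "build_vector_field",
]

AUTOREGULATION_DEFAULTS = {"V_max": 1.0, "K": 2.0, "k_d": 0.01, "beta": 4.0}
TOGGLE_SWITCH_DEFAULTS = {
    "alpha1": 5.0,
    "alpha2": 5.0,
    "beta1": 2.0,
    "beta2": 2.0,
    "q1": 1.0,
    "q2": 1.0,
    "k_d": 1.0,
}


def _require_positive(params: dict) -> None:
    for name, value in params.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"parameter {name} must be positive, got {value}")


# -- autoregulation -----------------------------------------------------------

def _autoreg_rhs(z, p):
    V_max, K, k_d, beta = p
    x = z[0]
    xb = x ** beta
    return np.array([V_max * xb / (K ** beta + xb) - k_d * x])


def _autoreg_div(z, p):
    V_max, K, k_d, beta = p
    x = z[0]
    Kb = K ** beta
    denom = (Kb + x ** beta) ** 2
    return V_max * beta * Kb * x ** (beta - 1.0) / denom - k_d


def _autoreg_rhs_batch(Z, P):
    x = Z[:, 0]
    V_max, K, k_d, beta = P[:, 0], P[:, 1], P[:, 2], P[:, 3]
    xb = x ** beta
    return (V_max * xb / (K ** beta + xb) - k_d * x)[:, None]


def _autoreg_div_batch(Z, P):
    x = Z[:, 0]
    V_max, K, k_d, beta = P[:, 0], P[:, 1], P[:, 2], P[:, 3]
    Kb = K ** beta
    return V_max * beta * Kb * x ** (beta - 1.0) / (Kb + x ** beta) ** 2 - k_d


def autoregulation_model() -> ParametricModel:
    """Autoregulated gene expression as a parametric model (state x >= 0)."""
    return ParametricModel(
        state_dim=1,
        param_dim=4,
        rhs_given_params=_autoreg_rhs,
        param_names=["V_max", "K", "k_d", "beta"],
        div_state=_autoreg_div,
        rhs_batch_given_params=_autoreg_rhs_batch,
        div_state_batch=_autoreg_div_batch,
        domain_lo=[0.0],
        defaults=dict(AUTOREGULATION_DEFAULTS),
        name="autoregulation",
    )


def build_autoregulation(
    V_max: float = 1.0, K: float = 2.0, k_d: float = 0.01, beta: float = 4.0
) -> VectorField:
    """One-dimensional autoregulation vector field with fixed parameters."""
    _require_positive({"V_max": V_max, "K": K, "k_d": k_d, "beta": beta})
    return bind_parameters(
        autoregulation_model(), V_max=V_max, K=K, k_d=k_d, beta=beta
    )


# -- toggle switch ------------------------------------------------------------

def _toggle_rhs(z, p):
    a1, a2, b1, b2, q1, q2, k_d = p
    x1, x2 = z
    return np.array(
        [
            a1 / (1.0 + (x2 / q1) ** b1) - k_d * x1,
            a2 / (1.0 + (x1 / q2) ** b2) - k_d * x2,
        ]
    )


def _toggle_div(z, p):
    # Each equation's own state enters only through dilution: div = -2 k_d.
    return -2.0 * p[6]


def _toggle_rhs_batch(Z, P):
    x1, x2 = Z[:, 0], Z[:, 1]
    a1, a2, b1, b2, q1, q2, k_d = (P[:, j] for j in range(7))
    return np.stack(
        [
            a1 / (1.0 + (x2 / q1) ** b1) - k_d * x1,
            a2 / (1.0 + (x1 / q2) ** b2) - k_d * x2,
        ],
        axis=1,
    )


def _toggle_div_batch(Z, P):
    return -2.0 * P[:, 6]


def toggle_switch_model() -> ParametricModel:
    """Genetic toggle switch as a parametric model (states x1, x2 >= 0)."""
    return ParametricModel(
        state_dim=2,
        param_dim=7,
        rhs_given_params=_toggle_rhs,
        param_names=["alpha1", "alpha2", "beta1", "beta2", "q1", "q2", "k_d"],
        div_state=_toggle_div,
        rhs_batch_given_params=_toggle_rhs_batch,
        div_state_batch=_toggle_div_batch,
        domain_lo=[0.0, 0.0],
        defaults=dict(TOGGLE_SWITCH_DEFAULTS),
        name="toggle_switch",
    )


def build_toggle_switch(
    alpha1: float = 5.0,
    alpha2: float = 5.0,
    beta1: float = 2.0,
    beta2: float = 2.0,
    q1: float = 1.0,
    q2: float = 1.0,
    k_d: float = 1.0,
) -> VectorField:
    """Two-dimensional toggle-switch vector field with fixed parameters."""
    _require_positive(
        {
            "alpha1": alpha1,
            "alpha2": alpha2,
            "beta1": beta1,
            "beta2": beta2,
            "q1": q1,
            "q2": q2,
            "k_d": k_d,
        }
    )
    return bind_parameters(
        toggle_switch_model(),
        alpha1=alpha1,
        alpha2=alpha2,
        beta1=beta1,
        beta2=beta2,
        q1=q1,
        q2=q2,
        k_d=k_d,
    )


# -- registry -----------------------------------------------------------------

MODEL_REGISTRY = {
    "autoregulation": autoregulation_model,
    "toggle_switch": toggle_switch_model,
}


def get_model(name: str) -> ParametricModel:
    try:
        return MODEL_REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None


def build_vector_field(name: str, **params: float) -> VectorField:
    """Bind a registered model's parameters, validating positivity."""
    model = get_model(name)
    merged = dict(model.defaults or {})
    merged.update(params)
    _require_positive(merged)
    return bind_parameters(model, **merged)
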