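import numpy as np
import pytest

import liouville as lv


@pytest.fixture(scope="session")
def autoreg():
    """Autoregulation field with the reference parameter set."""
    return lv.build_autoregulation(V_max=1.0, K=2.0, k_d=0.01, beta=4.0)


@pytest.fixture(scope="session")
def toggle():
    """Symmetric toggle switch with the reference parameter set."""
    return lv.build_toggle_switch(
        alpha1=5.0, alpha2=5.0, beta1=2.0, beta2=2.0, q1=1.0, q2=1.0, k_d=1.0
    )


@pytest.fixture(scope="session")
def u0_autoreg():
    """Initial protein-concentration density N(2, 0.2)."""
    return lv.NormalDensity([2.0], 0.2)


@pytest.fixture(scope="session")
def u0_toggle():
    """Initial toggle density N((3,3), diag(0.1, 0.1))."""
    return lv.NormalDensity([3.0, 3.0], [0.1, 0.1])


@pytest.fixture(scope="session")
def linear_decay():
    """dx/dt = -x with unit divergence magnitude: everything closed form."""
    return lv.VectorField(
        1,
        lambda x: -x,
        divergence=lambda x: -1.0,
        rhs_batch=lambda X: -X,
        divergence_batch=lambda X: np.full(X.shape[0], -1.0),
        name="linear_decay",
    )


@pytest.fixture(scope="session")
def planar_rotation():
    """Divergence-free rotation: density constant along trajectories."""
    return lv.VectorField(
        2,
        lambda x: np.array([-x[1], x[0]]),
        divergence=lambda x: 0.0,
        name="planar_rotation",
    )
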