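import numpy as np
import pytest
from hypothesis import settings

import sarscore as ss

settings.register_profile("suite", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def lattice10():
    """2x5 rook lattice: the R=10 synthetic spatial structure."""
    return ss.lattice_weights(2, 5)


@pytest.fixture
def lattice9():
    return ss.lattice_weights(3, 3)


def make_params(R, nu=5.0, phi=0.8, rho1=0.7, rho2=0.0, lam=0.0, kappa=0.5,
                beta=(0.0,)):
    return ss.ModelParameters(
        beta=np.asarray(beta, float),
        rho1=rho1,
        rho2=rho2,
        nu=nu,
        lam=np.full(R, lam, dtype=float),
        phi=phi,
        kappa=np.full(R, kappa, dtype=float),
    )


@pytest.fixture
def params10():
    return make_params(10)


@pytest.fixture
def panel10(params10, lattice10):
    cfg = ss.SimulationConfig(params=params10, W1=lattice10, T=600, seed=11)
    return ss.simulate_panel(cfg)


def random_instance(rng, R, rho2=None):
    """A random valid parameter set, weight matrices and one observation."""
    if R == 1:
        W = np.zeros((1, 1))
        rho1 = rho2v = 0.0
    else:
        A = rng.uniform(0.1, 1.0, size=(R, R))
        np.fill_diagonal(A, 0.0)
        W = ss.row_normalize(A)
        rho1 = rng.uniform(-0.8, 0.8)
        rho2v = rng.uniform(-0.8, 0.8) if rho2 is None else rho2
    params = ss.ModelParameters(
        beta=rng.normal(size=2),
        rho1=rho1,
        rho2=rho2v,
        nu=rng.uniform(2.0, 20.0),
        lam=rng.uniform(-0.5, 0.5, size=R),
        phi=rng.uniform(-0.9, 0.9),
        kappa=rng.uniform(0.1, 2.0, size=R),
    )
    X_t = np.column_stack([np.ones(R), rng.normal(size=R)])
    y_t = rng.normal(size=R) * 2.0
    mu_t = rng.normal(size=R)
    return params, W, X_t, y_t, mu_t
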