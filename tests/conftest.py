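import numpy as np
import pytest

from pbcunwrap.gaussian_model import GaussianModelParams, simulate


@pytest.fixture(scope="session")
def model_params():
    """Reference study conditions: sigma_L = 0.1 L, sigma_w = 0.05 L."""
    return GaussianModelParams(L=1.0, sigma_L=0.1, sigma_w=0.05, n_steps=2000, seed=11)


@pytest.fixture(scope="session")
def realization(model_params):
    return simulate(model_params)


@pytest.fixture(scope="session")
def axis_series(realization):
    """The realization's first particle/axis as plain 1D arrays (w, L, u, u*)."""
    w = realization.w.positions[:, 0, 0]
    L = realization.box.lengths[:, 0]
    u = realization.u_true.positions[:, 0, 0]
    us = realization.u_star.positions[:, 0, 0]
    return w, L, u, us


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
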