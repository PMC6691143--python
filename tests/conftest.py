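import numpy as np
import pytest

from boostmd import models


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def double_well():
    return models.make_double_well(5.0, 2.0)


@pytest.fixture(scope="session")
def cg_helix10():
    return models.make_cg_helix(10)


@pytest.fixture(scope="session")
def cg_helix15():
    return models.make_cg_helix(15)


def finite_difference_gradient(energy_fn, x, h=1e-6):
    """Central-difference gradient of a scalar energy function."""
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(x.shape[1]):
            xp = x.copy()
            xp[i, d] += h
            xm = x.copy()
            xm[i, d] -= h
            g[i, d] = (energy_fn(xp) - energy_fn(xm)) / (2.0 * h)
    return g
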