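import numpy as np
import pytest

from catrace.virtual_geometry import rebuild_chain


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_internal(rng, nres, theta_lo=20.0, theta_hi=178.0):
    """Random internal coordinates for an nres-atom chain."""
    d = np.full(nres - 1, 3.8)
    theta = rng.uniform(theta_lo, theta_hi, nres - 2)
    gamma = 180.0 - rng.uniform(0.0, 360.0, nres - 3)
    return d, theta, gamma


def random_chain_coords(rng, nres, **kw):
    d, theta, gamma = random_internal(rng, nres, **kw)
    return rebuild_chain(d, theta, gamma), theta, gamma
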