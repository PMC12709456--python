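import numpy as np
import pytest

from trophicbrain.hopf import HopfParameters


@pytest.fixture
def chain3():
    """Directed path 1->2->3 with unit weights."""
    C = np.zeros((3, 3))
    C[0, 1] = 1.0
    C[1, 2] = 1.0
    return C


@pytest.fixture
def chain5():
    """Directed path over 5 nodes with unit weights."""
    return np.diag(np.ones(4), 1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ou_params():
    """Scalar Ornstein-Uhlenbeck regime: a=-0.5, omega=0, sigma=0.1."""
    return HopfParameters(a=-0.5, omega=0.0, sigma=0.1, tau=1.0)


def random_coupling(n, rng, density=0.5, scale=0.05):
    """Random nonnegative coupling with zero diagonal (test helper)."""
    C = rng.uniform(0, scale, (n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(C, 0.0)
    if C.sum() == 0:
        C[0, 1] = scale
    return C
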