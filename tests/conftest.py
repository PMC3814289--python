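import numpy as np
import pytest

from lnakit import birth_death, erk_cascade, michaelis_menten


@pytest.fixture(scope="session")
def mm():
    """Michaelis–Menten fixture at its defaults (all rates 1, β=10, Ω=100)."""
    return michaelis_menten()


@pytest.fixture(scope="session")
def erk():
    """ERK MAPK cascade at reference parameters (K_I=45, V_cell=1e-14 l)."""
    return erk_cascade()


@pytest.fixture(scope="session")
def bd():
    return birth_death()


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_922)
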