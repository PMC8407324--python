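import numpy as np
import pytest

from phasedfba.presets import toy_study
from phasedfba.simulator import simulate


@pytest.fixture(scope="session")
def toy():
    """Reference toy study (network + default wine-like conditions)."""
    return toy_study()


@pytest.fixture(scope="session")
def batch(toy):
    """One full reference batch simulation with stored fluxes."""
    return simulate(toy.params, toy.network, toy.schedule, toy.init)


@pytest.fixture()
def fresh_toy():
    """Mutable copy of the toy study for tests that edit the network."""
    return toy_study()


@pytest.fixture(scope="session")
def short_study():
    """Compressed schedule for fast end-to-end runs (~20 h horizon)."""
    return toy_study(t_L=1.0, t_E=6.0, t_S=9.0, t_D=15.0, tF=20.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
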