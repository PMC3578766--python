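import numpy as np
import pytest
from hypothesis import settings

from stdpnet.window import STDPWindow, Pairing
from stdpnet.network import NeuronParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def balanced_window() -> STDPWindow:
    return STDPWindow(a_plus=0.005, a_minus=0.005, tau_plus=20.0, tau_minus=20.0, w_max=2.0)


@pytest.fixture(scope="session")
def shifted_window() -> STDPWindow:
    return STDPWindow(
        a_plus=0.005, a_minus=0.00284, tau_plus=20.0, tau_minus=20.0,
        shift=10.0, pairing=Pairing.NEAREST_NEIGHBOR, w_max=2.0,
    )


@pytest.fixture(scope="session")
def neuron() -> NeuronParams:
    return NeuronParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
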