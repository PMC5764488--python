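import numpy as np
import pytest
from hypothesis import settings

from qiffre.fre_models import FREParams, FREState

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig3_params() -> FREParams:
    """Reference inhibitory population: tau_m=10 ms, J=21, Theta=4, Delta=0.3."""
    return FREParams(tau_m=10.0, tau_d=5.0, J=21.0, Theta=4.0, Delta=0.3)


@pytest.fixture(scope="session")
def fig3_init() -> FREState:
    """Reference initial condition R(0) = S(0) = 5 Hz, V(0) = 0."""
    return FREState.from_hz(5.0, 0.0, 5.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
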