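import numpy as np
import pytest

from phorce.model import InitialState, PredationParams
from phorce.synth import SignalModel


@pytest.fixture
def base_params():
    """Reference kinetics: r_bac = 1/h, k_adsorb = 1e-9 mL/h, burst 100."""
    return PredationParams(r_bac=1.0, k_adsorb=1e-9, n_burst=100.0)


@pytest.fixture
def latency_params():
    return PredationParams(r_bac=1.0, k_adsorb=0.0, n_burst=100.0, tau_latency=0.5)


@pytest.fixture
def standard_init():
    return InitialState(b0=1e5, p0=1e5)


@pytest.fixture
def screen_init():
    """Single-condition screen well: b0 = 4e5, p0 = 1e5 per mL."""
    return InitialState(b0=4e5, p0=1e5)


@pytest.fixture
def quiet_signal():
    return SignalModel(noise_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
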