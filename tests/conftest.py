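import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def stim_params():
    from mecfes.stim_engine import StimParams
    return StimParams()


@pytest.fixture
def control_params():
    from mecfes.dsp_chain import ControlParams
    return ControlParams()


@pytest.fixture
def quiet_noise():
    """EMG-only noise model: no mains, no movement artifacts."""
    from mecfes.signal_model import NoiseModel
    return NoiseModel(mains_amp_mv=0.0, movement_artifact_rate_hz=0.0, rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
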