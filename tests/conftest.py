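import numpy as np
import pytest
from hypothesis import settings

from asicsim import ASICModelParams, NeuronParams
from asicsim.sweeps import burst_metrics_for_ramp
from asicsim.synthetic import SyntheticRecordingConfig, generate_protocol_suite

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def asic_params() -> ASICModelParams:
    return ASICModelParams()


@pytest.fixture(scope="session")
def neuron_params() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def fast_burst():
    """Current-clamp response to the 1-s-FT pH 7.4->6.0 sigmoid ramp."""
    res, mets = burst_metrics_for_ramp(6.0, 1.0, duration=30_000.0,
                                       record_aux=True)
    return res, mets


@pytest.fixture(scope="session")
def noiseless_suite():
    """Noise-free synthetic recordings of the full protocol suite."""
    cfg = SyntheticRecordingConfig(noise_sd=0.0, seed=0)
    return generate_protocol_suite(cfg), cfg


@pytest.fixture(scope="session")
def noisy_suite():
    """Moderately noisy synthetic recordings (fixed seed)."""
    cfg = SyntheticRecordingConfig(noise_sd=5.0, seed=1)
    return generate_protocol_suite(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
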