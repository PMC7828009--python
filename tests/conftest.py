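import numpy as np
import pytest

from phaseloop import SignalConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def alpha_record_10db():
    """A 30 s stochastic alpha record at 10 dB in-band SNR (2 kHz)."""
    return generate(SignalConfig(duration=30.0, snr_db=10.0, seed=7))


@pytest.fixture(scope="session")
def noiseless_record():
    """The same 30 s record with the noise disabled (identical oscillation)."""
    return generate(SignalConfig(duration=30.0, snr_db=float("inf"), seed=7))
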