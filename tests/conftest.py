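import numpy as np
import pytest

from eegxai.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synth():
    """Reduced-scale study conditions used across tests: 8 bipolar channels,
    128 Hz, three 60 s recordings with one 15 s seizure each, two
    informative channels at 3x background amplitude."""
    return SynthConfig(
        n_channels=8,
        fs=128.0,
        n_recordings=3,
        recording_duration=60.0,
        seizure_intervals=[(20.0, 35.0)],
        informative_channels=frozenset({0, 1}),
        ictal_band=(3.0, 20.0),
        ictal_amplitude=3.0,
        noise_model="pink",
        seed=7,
    )
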