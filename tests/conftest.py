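import numpy as np
import pytest

from qeegpred import simulate
from qeegpred.preprocess import make_epochs, bandpass_filter, common_average_reference


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_background():
    """8-s quiet 1/f background recording, 500 Hz, 19 channels."""
    return simulate.generate_background(duration_s=8.0, fs=500.0, seed=42)


@pytest.fixture(scope="session")
def car_epochs(short_background):
    """Common-average-referenced 2-s epochs of the short background."""
    rec = bandpass_filter(short_background)
    return common_average_reference(make_epochs(rec, 2.0, 8.0))


def sinusoid_recording(freq_hz, duration_s=8.0, fs=500.0, amp=1.0,
                       n_channels=19, phase=0.0):
    """Recording whose channels all carry the same sinusoid."""
    t = np.arange(int(duration_s * fs)) / fs
    x = amp * np.cos(2 * np.pi * freq_hz * t + phase)
    from qeegpred.core import EEGRecording

    return EEGRecording(data=np.tile(x, (n_channels, 1)), fs=fs)
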