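import numpy as np
import pytest

from perictal.io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(x, fs=1000.0, channels=None):
    x = np.atleast_2d(np.asarray(x, float))
    if channels is None:
        channels = ("HC", "mPFC")[: x.shape[0]]
    return Recording(x, fs, channels)


@pytest.fixture
def two_channel_noise(rng):
    fs = 1000.0
    return make_recording(rng.standard_normal((2, int(10 * fs))), fs)
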