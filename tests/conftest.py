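import numpy as np
import pytest

from imgtx.images import TimeSeriesVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A 6x6x6 x 40 white-noise volume on a 3-mm grid, TR = 2 s."""
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = -7.5
    data = rng.standard_normal((6, 6, 6, 40))
    return TimeSeriesVolume(data, affine, tr=2.0)


@pytest.fixture
def full_mask():
    return np.ones((6, 6, 6), bool)


def make_tone(freq_hz, n=200, tr=2.0, amplitude=1.0, phase=0.3):
    """A pure cosine sampled at TR; freq should sit on an exact DFT bin."""
    t = np.arange(n) * tr
    return amplitude * np.cos(2 * np.pi * freq_hz * t + phase)
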