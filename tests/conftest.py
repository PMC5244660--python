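import numpy as np
import pytest

from objcoloc.io_formats import ChannelImage, ImagePair


def make_pair(a, b, bit_depth=8):
    """Build an ImagePair from raw arrays (reshaped to 2D if flat)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim == 1:
        a = a.reshape(1, -1)
        b = b.reshape(1, -1)
    return ImagePair(
        ChannelImage(a, bit_depth, "channel_a", "test_A"),
        ChannelImage(b, bit_depth, "channel_b", "test_B"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_pair(rng):
    a = rng.integers(0, 256, size=(32, 32))
    b = rng.integers(0, 256, size=(32, 32))
    return make_pair(a, b)
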