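import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gray(rng):
    """A seeded 16x16 random grayscale image."""
    return rng.integers(0, 256, (16, 16)).astype(np.uint8)


@pytest.fixture
def checkerboard():
    """A 40x40 0/255 checkerboard (period 2)."""
    idx = np.indices((40, 40)).sum(axis=0)
    return ((idx % 2) * 255).astype(np.uint8)
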