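import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_connected_mask(rng, size=48, n_steps=120, dilate=1):
    """Random connected blob: dilated random-walk trace."""
    canvas = np.zeros((size, size), dtype=bool)
    pos = np.array([size // 2, size // 2])
    for _ in range(n_steps):
        canvas[pos[0], pos[1]] = True
        pos = pos + rng.integers(-1, 2, size=2)
        pos = np.clip(pos, 1, size - 2)
    if dilate:
        canvas = ndimage.binary_dilation(canvas, iterations=dilate)
    return canvas


@pytest.fixture
def random_mask_factory(rng):
    def make(size=48, n_steps=120, dilate=1):
        return random_connected_mask(rng, size, n_steps, dilate)
    return make
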