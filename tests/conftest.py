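import numpy as np
import pytest

from cbctfuse.core import PipelineConfig


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def step16():
    """16x16 vertical step edge: left half 0.2, right half 0.8."""
    img = np.full((16, 16), 0.2)
    img[:, 8:] = 0.8
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def random_image(rng, shape=(32, 32)):
    """Seeded random image in [0, 1] with a bit of spatial structure."""
    from scipy import ndimage

    base = rng.random(shape)
    smooth = ndimage.gaussian_filter(base, 1.5, mode="nearest")
    img = 0.6 * smooth + 0.4 * rng.random(shape)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)
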