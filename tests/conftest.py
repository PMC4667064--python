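import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_image(rng):
    """A 16x16 random image in [0, 1]."""
    return rng.random((16, 16))


@pytest.fixture
def smooth_image(rng):
    """A 16x16 smooth-ish image: blurred noise rescaled into [0.1, 0.9]."""
    from scipy import ndimage
    f = ndimage.gaussian_filter(rng.standard_normal((16, 16)), 2.0,
                                mode="reflect")
    f = (f - f.min()) / (f.max() - f.min())
    return 0.1 + 0.8 * f
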