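import numpy as np
import pytest
from skimage.draw import ellipse as _ellipse


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def ellipse_image():
    """Factory for binary ellipse images (frame, center, semi-axes, rotation)."""

    def make(frame, rc, cc, ra, ca, rot=0.0):
        img = np.zeros(frame)
        rr, cci = _ellipse(rc, cc, ra, ca, shape=frame, rotation=rot)
        img[rr, cci] = 1.0
        return img

    return make
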