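import numpy as np
import pytest

from echosr.image import USImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    def make(L=16, D=12, value_range=(0.0, 1.0)):
        lo, hi = value_range
        pix = rng.uniform(lo, hi, size=(L, D))
        return USImage(pixels=pix, value_range=value_range)

    return make
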