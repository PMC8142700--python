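import numpy as np
import pytest

from glavenstats import colorspace as cs


@pytest.fixture(scope="session")
def cal():
    return cs.default_calibration()


@pytest.fixture(scope="session")
def fundamentals():
    return cs.cone_fundamentals()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_lms_image(rng):
    """A small random positive LMS image."""
    return cs.ColorImage(rng.uniform(0.05, 1.0, (12, 10, 3)), "LMS")


def split_masks(shape, rng, p=0.4):
    """Two disjoint non-empty random masks over an image shape."""
    r = rng.uniform(0, 1, shape)
    filt = r < p
    unfilt = r >= p
    filt[0, 0], unfilt[0, 0] = True, False  # guarantee non-empty either way
    filt[-1, -1], unfilt[-1, -1] = False, True
    return cs.RegionMask(filt, "object"), cs.RegionMask(unfilt, "background")
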