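import numpy as np
import pytest

from atwkit.atw_metric import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_image(rgb, shape=(4, 4)):
    return np.full(shape + (3,), rgb, dtype=np.uint8)


@pytest.fixture
def red_image():
    return uniform_image((255, 0, 0))


@pytest.fixture
def blue_image():
    return uniform_image((0, 0, 255))
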