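import numpy as np
import pytest

from emas.intervals import Frame, from_mask


def random_mask(rng, shape, density=0.35):
    return rng.random(shape) < density


def random_domain(rng, shape, density=0.35, frame=None):
    return from_mask(random_mask(rng, shape, density), frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def frame2d():
    return Frame("test-2d", (12, 14))


@pytest.fixture
def frame3d():
    return Frame("test-3d", (6, 10, 12))
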