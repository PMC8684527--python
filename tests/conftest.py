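import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from focusfuse.imio import RasterImage
from focusfuse.synth import make_fixture


@pytest.fixture(scope="session")
def tiny_scene():
    """Fast 64x64 synthetic multifocus scene (seed 42, sigma 3)."""
    return make_fixture("tiny64", seed=42, blur_sigma=3.0)


@pytest.fixture(scope="session")
def gray512_scene():
    """The default full-size grayscale fixture (seed 42, sigma 3)."""
    return make_fixture("gray512", seed=42, blur_sigma=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return RasterImage(rng.uniform(0.0, 255.0, size=(32, 32)))


def constant_image(value=100.0, shape=(16, 16)):
    return RasterImage(np.full(shape, float(value)))


@pytest.fixture
def const_img():
    return constant_image()
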