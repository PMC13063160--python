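import numpy as np
import pytest

from sanqigrade import SliceImage, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return SliceImage(pixels=rng.random((24, 24, 3)))


@pytest.fixture
def constant_image():
    return SliceImage(pixels=np.full((16, 16, 3), 0.6))


@pytest.fixture(scope="session")
def synthetic_3grade():
    """A small synthetic slice dataset with the planted saponin-appearance link."""
    return gen_dataset(96, scheme=3, seed=11, size=(64, 64))
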