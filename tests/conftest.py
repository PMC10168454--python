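import numpy as np
import pytest

from shortcutscope import Image8, PhantomParams, generate_pool


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def random_images(rng):
    """50 small random-texture images for operator property tests."""
    return [
        Image8(rng.integers(0, 256, size=(16, 16)), id=f"rand-{i}")
        for i in range(50)
    ]


@pytest.fixture(scope="session")
def midrange_images(rng):
    """Images with intensities in [32, 223], away from clamp effects."""
    return [
        Image8(rng.integers(32, 224, size=(24, 24)), id=f"mid-{i}")
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def small_pool():
    """A quick phantom pool shared by training-level tests."""
    return generate_pool(240, PhantomParams(side=64, seed=11))
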