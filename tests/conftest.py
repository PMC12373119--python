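import numpy as np
import pytest

from organcolor import SyntheticConfig, generate_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_pairs():
    """Twenty 32×32 synthetic pairs shared by cheap training tests."""
    return generate_pairs(20, SyntheticConfig(size=32, seed=7))


@pytest.fixture
def random_rgb(rng):
    def make(size=64):
        return rng.integers(0, 256, (size, size, 3), dtype=np.uint8)

    return make
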