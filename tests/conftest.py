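import numpy as np
import pytest

from lapet import synthetic
from lapet.volume import VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_effects():
    """Planted-effects geometry on a small grid for fast volume tests."""
    return synthetic.GroundTruthEffects.default((20, 24, 20))


@pytest.fixture
def toy_volume():
    data = np.arange(4 * 5 * 6, dtype=float).reshape(4, 5, 6) + 1.0
    return VolumeImage(data, np.diag([4.0, 4.0, 4.0, 1.0]))
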