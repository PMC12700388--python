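import numpy as np
import pytest
from scipy import ndimage

from skeletrace.volume_io import BinaryVolume, ScalarVolume


@pytest.fixture(scope="session")
def smooth_random_volume():
    """Factory for seeded random smooth scalar fields (Gaussian-filtered noise)."""

    def make(shape=(24, 24, 24), seed=0, sigma=2.0):
        rng = np.random.default_rng(seed)
        return ScalarVolume(ndimage.gaussian_filter(rng.normal(size=shape), sigma))

    return make


@pytest.fixture
def small_shell():
    """One spherical shell, 64^3: radius 18, thickness 5."""
    x, y, z = np.meshgrid(*(np.arange(64),) * 3, indexing="ij")
    r = np.sqrt((x - 32) ** 2 + (y - 32) ** 2 + (z - 32) ** 2)
    return BinaryVolume((np.abs(r - 18) <= 2.5).astype(np.uint8), 1.0)


@pytest.fixture
def solid_ball():
    """Solid ball of radius 6 centered in a 32^3 grid."""
    x, y, z = np.meshgrid(*(np.arange(32),) * 3, indexing="ij")
    r = np.sqrt((x - 16) ** 2 + (y - 16) ** 2 + (z - 16) ** 2)
    return BinaryVolume((r <= 6).astype(np.uint8), 1.0)
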