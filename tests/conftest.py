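import numpy as np
import pytest

from drrmatch.imaging_io import CTVolume
from drrmatch.phantom import PhantomSpec, XraySimSpec, make_phantom, make_phantom_with_masks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_volume(rng, shape=(8, 8, 8), lo=-1000, hi=3000, spacing=(1.0, 1.0, 1.0)):
    vals = rng.integers(lo, hi, size=shape).astype(float)
    return CTVolume(vals, spacing)


@pytest.fixture(scope="session")
def default_phantom():
    """128-cube pelvis phantom at the package's default study conditions."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_with_bone():
    return make_phantom_with_masks(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_phantom():
    """48-cube phantom for speed-sensitive orchestration tests."""
    return make_phantom(PhantomSpec(shape=(48, 48, 48), seed=1))
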