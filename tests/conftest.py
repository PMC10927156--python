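import numpy as np
import pytest

from ambbem.layer_classifier import LayerClass
from ambbem.phantom import PhantomSpec, generate_phantom

#: Phantom size used across the unit tests; large enough for every
#: geometric feature, small enough to keep the suite fast.
TEST_SIZE = 128


@pytest.fixture(scope="session")
def single_region_phantom():
    return generate_phantom(PhantomSpec(image_size=TEST_SIZE, seed=3))


@pytest.fixture(scope="session")
def gapped_phantom():
    return generate_phantom(
        PhantomSpec(image_size=TEST_SIZE, n_skull_gaps=1, gap_width_px=2, seed=5))


@pytest.fixture(scope="session")
def basis_cranii_phantom():
    return generate_phantom(
        PhantomSpec(image_size=256, is_basis_cranii=True, seed=0))


@pytest.fixture(scope="session")
def phantom_per_class():
    def build(cls: LayerClass, **kw):
        kw.setdefault("image_size", TEST_SIZE)
        return generate_phantom(PhantomSpec(
            n_brain_regions=1 if cls == LayerClass.BASIS_CRANII else cls.n_regions,
            is_basis_cranii=cls == LayerClass.BASIS_CRANII, **kw))
    return build


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
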