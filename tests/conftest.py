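import numpy as np
import pytest

from ratlas_ia.schemes import ten_direction_scheme
from ratlas_ia.synthetic import make_brain_mask, make_phantom_atlas, small_spec


@pytest.fixture(scope="session")
def scheme():
    return ten_direction_scheme()


@pytest.fixture(scope="session")
def spec():
    return small_spec()


@pytest.fixture(scope="session")
def atlas(spec):
    return make_phantom_atlas(spec)


@pytest.fixture(scope="session")
def brain_mask(spec, atlas):
    return make_brain_mask(spec, atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
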