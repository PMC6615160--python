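import numpy as np
import pytest

from visconn.atlas import attach_spherical_masks, load_builtin_atlas


@pytest.fixture(scope="session")
def atlas():
    return load_builtin_atlas()


@pytest.fixture(scope="session")
def masked_atlas():
    return attach_spherical_masks(load_builtin_atlas(), radius=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240719)
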