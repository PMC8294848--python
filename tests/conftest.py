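import numpy as np
import pytest

from gridplace.codebooks import make_grid_codebook, make_modular_one_hot, normalize_l1


@pytest.fixture(scope="session")
def grid23():
    return make_grid_codebook([2, 3])


@pytest.fixture(scope="session")
def grid34():
    return make_grid_codebook([3, 4])


@pytest.fixture(scope="session")
def grid711_norm():
    return normalize_l1(make_grid_codebook([7, 11]))


@pytest.fixture(scope="session")
def mo23():
    return make_modular_one_hot([2, 3])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
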