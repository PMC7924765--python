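import numpy as np
import pytest

from neurogain import generate_synthetic_connectome, normalize_in_strength


@pytest.fixture(scope="session")
def small_sc():
    """12-node modular connectome, raw weights."""
    return generate_synthetic_connectome(n=12, n_modules=3, p_intra=0.8, p_inter=0.15, seed=7)


@pytest.fixture(scope="session")
def small_sc_norm(small_sc):
    return normalize_in_strength(small_sc)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
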