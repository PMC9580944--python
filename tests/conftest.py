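import numpy as np
import pytest

from synthrna.fold import get_oracle
from synthrna.synthdata import fixed_length, make_dataset


@pytest.fixture(scope="session")
def oracle():
    return get_oracle("turner")


@pytest.fixture(scope="session")
def fallback_oracle():
    return get_oracle("fallback")


@pytest.fixture(scope="session")
def small_bundle(oracle):
    """60 oracle-folded random length-40 sequences (shared across tests)."""
    return make_dataset(60, fixed_length(40), seed=11, oracle=oracle)


@pytest.fixture(scope="session")
def tiny_bundle30(oracle):
    """30 oracle-folded random length-30 sequences."""
    return make_dataset(30, fixed_length(30), seed=7, oracle=oracle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
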