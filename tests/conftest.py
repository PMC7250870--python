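import numpy as np
import pytest

from acbm.fixtures import toy_model, toy_model_with_genes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy():
    return toy_model()


@pytest.fixture
def toy_genes():
    return toy_model_with_genes()
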