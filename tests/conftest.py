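import numpy as np
import pytest

from corrinv.signals import gen_fig1_dataset


@pytest.fixture(scope="session")
def fig1_batch():
    """Shared three-group dataset (sparse / OU network / white background)."""
    return gen_fig1_dataset(200_000, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
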