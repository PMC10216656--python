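import numpy as np
import pytest

from p3dstage.synthdsa import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_dataset():
    """Small shared phantom dataset (12 samples per stage, default params)."""
    return generate_dataset(12, master_seed=99)
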