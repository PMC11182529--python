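import numpy as np
import pytest

from deepgcl import synthetic_data as sd
from deepgcl.fusion_trainer import make_split, prepare_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """20-drug in-memory fixture: (records, class labels, network)."""
    return sd.make_dataset("tiny")


@pytest.fixture(scope="session")
def small_dataset():
    """100-drug in-memory fixture used for training smoke tests."""
    return sd.make_dataset("small")


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    records, _, net = small_dataset
    split = make_split(net, seed=3)
    return prepare_dataset(records, split, hop=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
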