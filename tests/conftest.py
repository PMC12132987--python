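import numpy as np
import pytest

from bnt.data import SemicontinuousDataset
from helpers import random_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_dataset():
    """Four rows, intercept-only designs, two zeros and two positives."""
    x = np.array([0.0, 0.0, 2.0, 3.1])
    Z = np.ones((4, 1))
    return SemicontinuousDataset(x, (x != 0).astype(int), Z, Z)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, n=40, q=3)
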