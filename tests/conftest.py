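import numpy as np
import pytest
from hypothesis import settings

from itermask.msa import Alphabet, Msa
from itermask.synthetic import random_potts_model

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def binary_alphabet():
    return Alphabet("A-")


@pytest.fixture
def toy3_alphabet():
    return Alphabet("AC-")


@pytest.fixture
def tiny_potts():
    """Random L=3, q=2 Potts model with full coupling density."""
    return random_potts_model(3, 2, coupling_density=1.0, coupling_scale=0.5,
                              field_scale=0.5, seed=1)


@pytest.fixture
def random_msa(binary_alphabet):
    rng = np.random.default_rng(11)
    data = rng.integers(0, 2, size=(40, 8)).astype(np.int16)
    return Msa([f"s{k}" for k in range(40)], data, binary_alphabet)


def state_index(data, q):
    """Encode sequences as integers for histogramming tiny state spaces."""
    L = data.shape[1]
    weights = q ** np.arange(L - 1, -1, -1)
    return data @ weights


def empirical_state_freqs(data, q):
    idx = state_index(np.asarray(data), q)
    counts = np.bincount(idx, minlength=q ** data.shape[1])
    return counts / counts.sum()
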