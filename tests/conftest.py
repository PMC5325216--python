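import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ndlkit import LearnerConfig, WeightMatrix, equilibrium_weights, toy_lexicon, train


@pytest.fixture(scope="session")
def toy_stream():
    return toy_lexicon()


@pytest.fixture(scope="session")
def toy_equilibrium(toy_stream):
    return equilibrium_weights(toy_stream)


@pytest.fixture(scope="session")
def toy_trained_300(toy_stream):
    """Incremental training, 300 shuffled frequency-proportional passes."""
    return train(toy_stream, LearnerConfig(passes=300, shuffle_seed=7))


@pytest.fixture
def random_sparse_matrix():
    """A reproducible sparse-ish random weight matrix with labeled axes."""

    def make(k=12, n=9, density=0.4, seed=0):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(k, n))
        arr[rng.random((k, n)) > density] = 0.0
        cues = [f"cue{i}" for i in range(k)]
        outs = [f"out{j}" for j in range(n)]
        return WeightMatrix(cues, outs, arr), arr, cues, outs

    return make
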