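import numpy as np
import pytest

from chebseg import (NetworkConfig, PhantomSpec, generate_phantom,
                     make_graph_sample)
from chebseg.pipeline import preprocess_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(height=64, width=64, seed=3)


@pytest.fixture(scope="session")
def phantom_case(small_spec):
    return generate_phantom(small_spec, 3)


@pytest.fixture(scope="session")
def normalized_slice(phantom_case):
    ct_slice, masks = preprocess_phantom(phantom_case)
    return ct_slice, masks


@pytest.fixture(scope="session")
def liver_sample(normalized_slice):
    ct_slice, masks = normalized_slice
    return make_graph_sample(ct_slice, masks["liver"], n_regions=120)


@pytest.fixture()
def tiny_config() -> NetworkConfig:
    return NetworkConfig(epochs=5, seed=11, folds=2)


def random_weighted_graph(rng: np.random.Generator, n: int,
                          edge_prob: float = 0.6) -> np.ndarray:
    """Random connected-ish symmetric nonnegative weight matrix, zero diagonal."""
    w = rng.random((n, n)) * (rng.random((n, n)) < edge_prob)
    w = np.triu(w, 1)
    # chain guarantees lambda_max > 0 and connectivity
    for i in range(n - 1):
        if w[i, i + 1] == 0:
            w[i, i + 1] = 0.5
    return w + w.T
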