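import numpy as np
import pytest

from hetmda.data_io import AssociationMatrix
from hetmda.embedding import EmbeddingParams, WalkParams
from hetmda.hetnet import build_heterogeneous_network
from hetmda.similarity import disease_similarity, microbe_similarity


@pytest.fixture
def assoc_3x4():
    """Hand-built 3 diseases x 4 microbes association matrix."""
    values = np.array(
        [
            [1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 1.0],
        ]
    )
    return AssociationMatrix(["dA", "dB", "dC"], ["m1", "m2", "m3", "m4"], values)


@pytest.fixture
def random_assoc():
    """Factory for random binary association matrices (never all-zero)."""

    def make(n_d, n_m, density=0.3, seed=0):
        rng = np.random.default_rng(seed)
        values = (rng.random((n_d, n_m)) < density).astype(float)
        if values.sum() == 0:
            values[rng.integers(n_d), rng.integers(n_m)] = 1.0
        diseases = [f"d{j}" for j in range(n_d)]
        microbes = [f"m{i}" for i in range(n_m)]
        return AssociationMatrix(diseases, microbes, values)

    return make


@pytest.fixture
def small_net(assoc_3x4):
    sm = microbe_similarity(assoc_3x4)
    sd = disease_similarity(assoc_3x4)
    return build_heterogeneous_network(sd, sm, assoc_3x4)


@pytest.fixture
def fast_walk_params():
    """Cheap walk settings for unit tests."""
    return WalkParams(p=0.5, q=4.0, walk_length=6, walks_per_node=3, seed=11)


@pytest.fixture
def fast_emb_params():
    """Cheap skip-gram settings for unit tests."""
    return EmbeddingParams(dimension=16, context_size=4, epochs=3, seed=11)
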