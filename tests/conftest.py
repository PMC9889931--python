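import numpy as np
import pytest

from semflex import EmbeddingModel, ToyEmbeddingConfig, make_toy_embeddings


@pytest.fixture(scope="session")
def toy_model() -> EmbeddingModel:
    """Two well-separated planted clusters of five tokens each."""
    return make_toy_embeddings(
        ToyEmbeddingConfig(
            n_clusters=2, tokens_per_cluster=5, dimension=8, within_cluster_spread=0.1, seed=42
        )
    )


@pytest.fixture
def axis_model() -> EmbeddingModel:
    """Hand-built 2-d space with exactly known geometry for arithmetic checks."""
    s = np.sqrt(2) / 2
    return EmbeddingModel(
        vectors={
            "east": np.array([1.0, 0.0]),
            "north": np.array([0.0, 1.0]),
            "northeast": np.array([s, s]),
            "west": np.array([-1.0, 0.0]),
        },
        dimension=2,
        source_tag="hand-built",
    )
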