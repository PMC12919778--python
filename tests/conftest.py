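import numpy as np
import pandas as pd
import pytest

from flens import EmbeddingSet, SyntheticConfig, gen_embeddings


@pytest.fixture
def small_set() -> EmbeddingSet:
    """3 items, 4 features, one metadata column."""
    rng = np.random.default_rng(42)
    return EmbeddingSet(
        ids=["tile_a", "tile_b", "tile_c"],
        features=rng.normal(size=(3, 4)),
        metadata=pd.DataFrame({"site": ["s1", "s2", "s1"]}),
    )


@pytest.fixture(scope="session")
def strong_batch_set() -> EmbeddingSet:
    """Synthetic embeddings with dominant site signal (delta/sigma = 10)."""
    return gen_embeddings(
        SyntheticConfig(delta=10.0, sigma=1.0, seed=11, tiles_per_slide=10)
    )


@pytest.fixture(scope="session")
def null_batch_set() -> EmbeddingSet:
    """Synthetic embeddings with no site signal (delta = 0)."""
    return gen_embeddings(
        SyntheticConfig(delta=0.0, sigma=1.0, seed=12, tiles_per_slide=10)
    )
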