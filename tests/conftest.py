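import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stfusion as sf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_counts() -> sf.CountMatrix:
    """4 spots x 2 genes: the worked C-score example (5' constant, 3' spiked)."""
    return sf.CountMatrix(
        counts=pd.DataFrame(
            {"SLC45A3": [2, 2, 2, 2], "ELK4": [1, 1, 1, 9]},
            index=["1x1", "2x1", "1x2", "2x2"],
        ),
        sample="toy",
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic section (seed 1), shared across tests."""
    cfg = sf.SyntheticConfig(seed=1)
    cm, fa, truth = sf.simulate_tissue(cfg)
    return cfg, cm, fa, truth


def random_count_matrix(rng: np.random.Generator, n_spots=None, n_genes=None):
    """Small random count matrix for oracle comparisons."""
    n_spots = n_spots or int(rng.integers(3, 12))
    n_genes = n_genes or int(rng.integers(2, 8))
    counts = rng.integers(0, 20, size=(n_spots, n_genes))
    index = [f"{i + 1}x1" for i in range(n_spots)]
    genes = [f"g{j}" for j in range(n_genes)]
    return sf.CountMatrix(
        counts=pd.DataFrame(counts, index=index, columns=genes), sample="rnd"
    )
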