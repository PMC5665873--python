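import numpy as np
import pandas as pd
import pytest

from exfoliomics.matrix import CountMatrix
from exfoliomics.simulate import SimulationParams, simulate_counts

SMALL_PARAMS = dict(n_genes=800, hk_gene_count=100, seed=0)


def make_count_matrix(counts, sample_prefix="s", groups=None):
    """CountMatrix from a 2-D array; optional group labels attach metadata."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    meta = None
    if groups is not None:
        meta = pd.DataFrame(
            {
                "source": "toy",
                "group": list(groups),
                "subject": [f"m{j}" for j in range(counts.shape[1])],
            },
            index=pd.Index(samples, name="sample_id"),
        )
    return CountMatrix(frame, meta)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-structure simulation at desk scale, shared across tests."""
    return simulate_counts(SimulationParams(**SMALL_PARAMS))


@pytest.fixture(scope="session")
def default_dataset():
    """Full default simulation parameters (2000 genes)."""
    return simulate_counts(SimulationParams(seed=11))
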