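import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from seepcomm import CommunityTable, SimulationConfig, simulate_dataset


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — patristic d(A,B)=2, d(A,C)=d(B,C)=4."""
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def paired_clade_tree():
    """Two sister pairs on long stems: ((A,B),(C,D))."""
    return TreeNode.read(["((A:0.1,B:0.1):1.0,(C:0.1,D:0.1):1.0);"])


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        {"S1": [4, 3, 3], "S2": [1, 1, 8], "S3": [5, 4, 0]},
        index=["A", "B", "C"],
    )
    return CommunityTable(df)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset (2 regimes not needed here)."""
    cfg = SimulationConfig(
        n_taxa=40,
        n_sites=2,
        n_depths_per_site=4,
        sequencing_depth=400,
        seed=7,
    )
    table, metadata, tree, truth = simulate_dataset(cfg)
    return {"table": table, "metadata": metadata, "tree": tree, "truth": truth}


def random_table(rng, n_taxa=8, n_samples=4, max_count=20) -> CommunityTable:
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    # make sure no sample is empty and every sample has >= 2 taxa
    counts[0, :] = np.maximum(counts[0, :], 1)
    counts[1, :] = np.maximum(counts[1, :], 1)
    df = pd.DataFrame(
        counts,
        index=[f"T{i:04d}" for i in range(n_taxa)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return CommunityTable(df)
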