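import numpy as np
import pandas as pd
import pytest

from eselect import EPMatrix


@pytest.fixture
def micro_matrix():
    """4 cell types x 3 enhancers worked example with hand-derived scores."""
    return EPMatrix(
        gene="g",
        cell_types=["c1", "c2", "c3", "c4"],
        enhancer_ids=["chr1:100-300", "chr1:500-700", "chr1:900-1100"],
        x=np.array([[1, 1, 0], [1, 0, 0], [1, 0, 1], [0, 0, 0]]),
    )


@pytest.fixture
def toy_interactions():
    """Three genes over three cell types; gene g3 has a single enhancer."""
    rows = [
        ("chr1", 100, 300, "chr1:100-300", "g1", "c1"),
        ("chr1", 100, 300, "chr1:100-300", "g1", "c2"),
        ("chr1", 500, 700, "chr1:500-700", "g1", "c1"),
        ("chr2", 100, 300, "chr2:100-300", "g2", "c2"),
        ("chr2", 500, 700, "chr2:500-700", "g2", "c3"),
        ("chr2", 900, 1100, "chr2:900-1100", "g3", "c1"),
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "enhancer_id", "gene", "cell_type"]
    )


def random_binary_matrix(rng, max_m=100, max_n=200):
    """Random EPMatrix with at least 2 enhancers, every column nonzero."""
    M = int(rng.integers(2, max_m + 1))
    N = int(rng.integers(2, max_n + 1))
    x = (rng.random((M, N)) < rng.uniform(0.05, 0.95)).astype(np.int8)
    for j in np.flatnonzero(x.sum(axis=0) == 0):
        x[rng.integers(M), j] = 1
    return EPMatrix(
        gene="g",
        cell_types=[f"c{i}" for i in range(M)],
        enhancer_ids=[f"chr1:{1000 * j}-{1000 * j + 500}" for j in range(N)],
        x=x,
    )
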