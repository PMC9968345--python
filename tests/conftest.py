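import numpy as np
import pandas as pd
import pytest

from scnavar.io import CountMatrix


@pytest.fixture
def toy_genes():
    """Six genes on two chromosomes, deliberately unsorted."""
    return pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
        "chrom": ["2", "1", "1", "2", "1", "2"],
        "start": [500, 300, 100, 100, 200, 900],
        "end": [600, 400, 150, 200, 250, 950],
    })


@pytest.fixture
def toy_annotation(toy_genes):
    return toy_genes.copy()


@pytest.fixture
def toy_counts(toy_genes):
    rng = np.random.default_rng(0)
    values = rng.poisson(2.0, size=(10, 6)).astype(float)
    values[values == 0] = 1.0  # every gene detected everywhere
    cells = [f"c{i}" for i in range(10)]
    return CountMatrix(values, cells, toy_genes[["gene_id"]].copy())


@pytest.fixture
def piecewise_matrix():
    """20 cells x 120 genes with two strong shared steps at 40 and 80."""
    rng = np.random.default_rng(42)
    m, n = 20, 120
    x = rng.normal(0.0, 0.2, size=(m, n))
    x[:, 40:80] += 3.0
    return x
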