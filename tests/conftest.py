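import numpy as np
import pytest
import scipy.sparse as sp

from cellshift.io import CountMatrix


def make_counts(dense, gene_ids=None, barcodes=None, gene_symbols=None) -> CountMatrix:
    """Build a CountMatrix from a dense genes x cells array."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"C{i}" for i in range(n_cells)]
    return CountMatrix(sp.csc_matrix(dense), gene_ids, barcodes, gene_symbols)


def random_counts(rng, n_genes=20, n_cells=10, density=0.4, max_count=8) -> CountMatrix:
    dense = rng.integers(1, max_count + 1, size=(n_genes, n_cells))
    dense[rng.random((n_genes, n_cells)) > density] = 0
    return make_counts(dense)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_counts():
    # 3 genes x 2 cells; entries (g1,c1)=5, (g3,c2)=1
    dense = np.array([[5, 0], [0, 0], [0, 1]])
    return make_counts(dense, gene_ids=["g1", "g2", "g3"], barcodes=["c1", "c2"])
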