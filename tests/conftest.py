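import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from synoclone.datatypes import CellGeneMatrix, ClusterAssignment
from synoclone.synthetic import demo_dataset


@pytest.fixture(scope="session")
def demo():
    """The default ~2,000-cell demo fixture with 5% doublets (seed 11)."""
    return demo_dataset(seed=11, doublet_rate=0.05)


@pytest.fixture(scope="session")
def demo_clean():
    """Doublet-free demo fixture (seed 11)."""
    return demo_dataset(seed=11, doublet_rate=0.0)


@pytest.fixture
def truth_assignment(demo):
    matrix, _, truth = demo
    labels = pd.Series({b: truth.cell_cluster[b] for b in matrix.barcodes})
    return ClusterAssignment(labels=labels.loc[matrix.barcodes], round_id="truth")


def make_matrix(counts, gene_symbols, barcodes=None, meta=None):
    """Small dense-counts helper for hand-constructed cases."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    assert n_genes == len(gene_symbols)
    if barcodes is None:
        barcodes = [f"BC{i:04d}-1" for i in range(n_cells)]
    return CellGeneMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"G{i:04d}" for i in range(n_genes)],
        gene_symbols=list(gene_symbols),
        barcodes=list(barcodes),
        cell_meta=meta,
    )
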