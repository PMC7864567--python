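import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp


def make_adata(counts, obs=None, genes=None, cells=None):
    """AnnData from a dense count array with consistent detection metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cells = cells or [f"c{i}" for i in range(n_cells)]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    obs = pd.DataFrame(index=cells) if obs is None else obs.set_axis(cells)
    obs["n_genes_detected"] = (counts > 0).sum(axis=1)
    obs["n_umis"] = counts.sum(axis=1)
    return ad.AnnData(
        X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=genes)
    )


def cell_row(n_genes_detected, n_umis, n_genes_total):
    """A count row with exactly the requested detection count and total."""
    row = np.zeros(n_genes_total, dtype=int)
    assert n_umis >= n_genes_detected
    row[:n_genes_detected] = 1
    row[0] += n_umis - n_genes_detected
    return row


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
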