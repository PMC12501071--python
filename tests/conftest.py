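import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from snatlas.io import CountMatrix


def make_count_matrix(counts, gene_ids=None, barcodes=None, samples=None,
                      celltypes=None, gene_pos=None) -> CountMatrix:
    """Build a CountMatrix from a dense genes x cells array with defaults."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"C{j}" for j in range(n_cells)]
    meta = pd.DataFrame({
        "sample": samples if samples is not None else ["S0"] * n_cells,
    }, index=pd.Index(barcodes, name="barcode"))
    if celltypes is not None:
        meta["celltype"] = celltypes
    return CountMatrix(counts=sp.csr_matrix(counts),
                       gene_ids=np.asarray(gene_ids, dtype=object),
                       barcodes=np.asarray(barcodes, dtype=object),
                       metadata=meta, gene_pos=gene_pos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cm(rng):
    """60 genes x 40 cells Poisson counts over two samples."""
    counts = rng.poisson(2.0, size=(60, 40))
    return make_count_matrix(counts,
                             samples=["S0"] * 20 + ["S1"] * 20)
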