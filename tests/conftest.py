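import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lnmet import CellTable, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One generator run at the standard study conditions, shared read-only."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture()
def toy_table():
    """Tiny dense 4-cell x 5-gene raw table with full metadata."""
    counts = np.array(
        [
            [5, 0, 3, 2, 0],
            [1, 1, 1, 1, 1],
            [0, 0, 10, 0, 0],
            [2, 2, 2, 2, 2],
        ]
    )
    cells = pd.DataFrame(
        {
            "patient": ["P1"] * 4,
            "tissue": ["PT", "PT", "LNMT", "LNMT"],
            "cluster": [0, 0, 1, 1],
            "doublet_score": [0.1, 0.2, 0.1, 0.3],
        },
        index=pd.Index([f"c{i}" for i in range(4)], name="cell_id"),
    )
    genes = pd.DataFrame(
        {
            "chromosome": ["chr1"] * 3 + ["chr2"] * 2,
            "start": [100, 200, 300, 100, 200],
        },
        index=pd.Index([f"g{i}" for i in range(5)], name="symbol"),
    )
    return CellTable(counts=sp.csr_matrix(counts), cell_meta=cells, gene_meta=genes)


def make_table(counts, clusters=None, patients=None, tissues=None, layer="raw",
               doublet_scores=None, gene_prefix="g"):
    """Helper to build a CellTable from a dense array with minimal metadata."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = pd.DataFrame(
        {
            "patient": patients if patients is not None else ["P1"] * n,
            "tissue": tissues if tissues is not None else ["PT"] * n,
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    if clusters is not None:
        cells["cluster"] = clusters
    if doublet_scores is not None:
        cells["doublet_score"] = doublet_scores
    genes = pd.DataFrame(
        index=pd.Index([f"{gene_prefix}{j}" for j in range(g)], name="symbol")
    )
    return CellTable(counts=sp.csr_matrix(counts), cell_meta=cells,
                     gene_meta=genes, layer=layer)
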