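"""Core in-memory container for cell-by-gene count data.

A :class:`CellTable` holds one matrix (cells x genes) plus per-cell and
per-gene metadata, tagged with the processing layer it represents:

* ``raw``      — non-negative integer UMI counts as loaded or simulated;
* ``adjusted`` — counts after ambient-contamination subtraction;
* ``lognorm``  — ln(1 + scale * x / N_c) normalized expression.

The container is deliberately thin; :meth:`CellTable.to_anndata` bridges to
the scanpy ecosystem for anything beyond the pipeline implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

LAYERS = ("raw", "adjusted", "lognorm")

#: per-cell metadata columns that are always present
CELL_META_REQUIRED = ("patient", "tissue")


class FormatError(ValueError):
    """Input files or tables are inconsistent with the declared dialect."""


@dataclass
class CellTable:
    """Cells x genes matrix with aligned metadata.

    Parameters
    ----------
    counts
        Sparse (CSR) or dense matrix, shape ``(n_cells, n_genes)``. Integer
        valued for ``raw``/``adjusted`` layers, float for ``lognorm``.
    cell_meta
        DataFrame indexed by unique ``cell_id``. Expected columns:
        ``patient``, ``tissue``; optional: ``cluster``, ``doublet_score``,
        ``total_umi``.
    gene_meta
        DataFrame indexed by unique gene ``symbol``. Optional columns:
        ``chromosome``, ``start``.
    layer
        One of ``raw``, ``adjusted``, ``lognorm``.
    """

    counts: sp.spmatrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    layer: str = "raw"

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise FormatError(
                f"cell_meta has {len(self.cell_meta)} rows but matrix has {n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise FormatError(
                f"gene_meta has {len(self.gene_meta)} rows but matrix has {n_genes} genes"
            )
        if self.cell_meta.index.has_duplicates:
            raise FormatError("cell ids are not unique")
        if self.gene_meta.index.has_duplicates:
            raise FormatError("gene symbols are not unique")
        if self.layer == "raw" and self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("raw counts contain negative entries")

    # ------------------------------------------------------------------ #

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_symbols(self) -> pd.Index:
        return self.gene_meta.index

    def cell_totals(self) -> np.ndarray:
        """Row sums of the current matrix (UMI depth on count layers)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_indexer(self, symbols: Iterable[str]) -> np.ndarray:
        """Positional indices of ``symbols``; raises KeyError on misses."""
        idx = self.gene_meta.index.get_indexer(list(symbols))
        if (idx < 0).any():
            missing = [s for s, i in zip(symbols, idx) if i < 0]
            raise KeyError(f"gene symbols not found: {missing}")
        return idx

    def subset_cells(self, mask_or_ids) -> "CellTable":
        """New table restricted to a boolean mask or list of cell ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            pos = np.flatnonzero(mask_or_ids)
        else:
            pos = self.cell_meta.index.get_indexer(list(mask_or_ids))
            if (pos < 0).any():
                raise KeyError("unknown cell ids in subset")
        return replace(
            self,
            counts=self.counts[pos],
            cell_meta=self.cell_meta.iloc[pos].copy(),
            gene_meta=self.gene_meta,
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_anndata(self):
        """Bridge to an :class:`anndata.AnnData` (obs=cells, var=genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
            uns={"layer": self.layer},
        )


def mito_mask(gene_meta: pd.DataFrame, prefix: str = "MT-") -> np.ndarray:
    """Boolean mask of mitochondrial genes by symbol prefix (case-insensitive)."""
    return np.asarray(gene_meta.index.str.upper().str.startswith(prefix.upper()))
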