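"""Input readers, per-sample cell QC, cluster-level doublet removal, and a
marker-set ambient-mRNA estimator/corrector.

The QC stage applies three per-sample filters to raw counts:

1. drop cells whose detected-gene number (log10) falls below the sample
   median minus ``mad_multiplier`` x MAD;
2. drop cells whose mitochondrial fraction exceeds the sample median plus
   ``mad_multiplier`` x MAD;
3. drop cells with fewer than ``umi_floor`` total UMIs.

"Sample" means a (patient, tissue) pair; MAD is the raw median absolute
deviation without a consistency constant. After QC, clusters dominated by
doublets are removed wholesale (mean doublet score above a threshold, or
markers of more than one cell type expressed). Finally, ambient
contamination is estimated from marker gene sets in clusters that cannot
biologically express them, and subtracted from the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .containers import CellTable, FormatError, mito_mask


class EmptyInputError(ValueError):
    pass


class EstimationError(ValueError):
    pass


# --------------------------------------------------------------------------- #
# reading


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> CellTable:
    """Read a MatrixMarket cells x genes matrix with TSV metadata sheets.

    ``genes.tsv`` must carry a ``symbol`` column (``chromosome``/``start``
    optional); ``cells.tsv`` a ``cell_id`` column (``patient``, ``tissue``,
    ``cluster``, ``doublet_score``, ``total_umi`` optional). Gzipped variants
    of the TSVs are accepted transparently by pandas.
    """
    counts = sp.csr_matrix(mmread(str(matrix_path)))
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    if "symbol" not in genes.columns:
        raise FormatError("genes.tsv must have a 'symbol' column")
    if "cell_id" not in cells.columns:
        raise FormatError("cells.tsv must have a 'cell_id' column")
    genes = genes.set_index("symbol")
    cells = cells.set_index("cell_id")
    if counts.shape != (len(cells), len(genes)):
        raise FormatError(
            f"matrix is {counts.shape} but metadata declares "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    if counts.nnz:
        counts.data = np.asarray(counts.data)
        if not np.issubdtype(counts.dtype, np.integer):
            if np.allclose(counts.data, np.rint(counts.data)):
                counts = counts.astype(np.int64)
            else:
                raise FormatError("raw count matrix has non-integer entries")
    return CellTable(counts=counts, cell_meta=cells, gene_meta=genes, layer="raw")


# --------------------------------------------------------------------------- #
# cell filters


@dataclass(frozen=True)
class QcThresholds:
    """Parameters of the three per-sample cell filters."""

    mad_multiplier: float = 3.0
    umi_floor: int = 300
    log10_genes: bool = True
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")
        if self.umi_floor < 0:
            raise ValueError("umi_floor must be non-negative")


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def filter_cells(
    table: CellTable, thr: QcThresholds = QcThresholds()
) -> tuple[CellTable, dict]:
    """Apply the three QC rules per (patient, tissue) sample.

    Returns the surviving table and a report with per-rule removal counts
    (a cell failing several rules is counted under each).
    """
    if table.layer != "raw":
        raise ValueError("filter_cells expects the raw layer")
    if table.n_cells == 0:
        raise EmptyInputError("empty cell table")

    totals = table.cell_totals().astype(float)
    n_genes_det = np.asarray((table.counts > 0).sum(axis=1)).ravel().astype(float)
    mmask = mito_mask(table.gene_meta, thr.mito_prefix)
    mito_counts = (
        np.asarray(table.counts[:, mmask].sum(axis=1)).ravel().astype(float)
        if mmask.any()
        else np.zeros(table.n_cells)
    )
    mito_frac = np.divide(mito_counts, totals, out=np.zeros_like(totals), where=totals > 0)
    genes_stat = np.log10(np.maximum(n_genes_det, 1.0)) if thr.log10_genes else n_genes_det

    fail_genes = np.zeros(table.n_cells, dtype=bool)
    fail_mito = np.zeros(table.n_cells, dtype=bool)
    sample_keys = ["patient", "tissue"]
    groups = (
        table.cell_meta.groupby(sample_keys, sort=True).indices.items()
        if set(sample_keys) <= set(table.cell_meta.columns)
        else [(("all",), np.arange(table.n_cells))]
    )
    for _, idx in groups:
        idx = np.asarray(idx)
        g = genes_stat[idx]
        fail_genes[idx] = g < np.median(g) - thr.mad_multiplier * _mad(g)
        m = mito_frac[idx]
        fail_mito[idx] = m > np.median(m) + thr.mad_multiplier * _mad(m)
    fail_umi = totals < thr.umi_floor

    removed = fail_genes | fail_mito | fail_umi
    kept = ~removed
    report = {
        "n_input": int(table.n_cells),
        "removed_low_genes": int(fail_genes.sum()),
        "removed_high_mito": int(fail_mito.sum()),
        "removed_low_umi": int(fail_umi.sum()),
        "n_removed": int(removed.sum()),
        "n_kept": int(kept.sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    return table.subset_cells(kept), report


# --------------------------------------------------------------------------- #
# doublet-cluster rule


@dataclass(frozen=True)
class DoubletRuleParams:
    """Cluster-level doublet removal rule.

    A cluster is removed when its mean doublet score exceeds
    ``score_threshold`` OR it expresses markers of more than
    ``max_marker_types`` distinct cell types. A cluster "expresses" a marker
    when more than ``expr_cell_frac`` of its cells have at least one count.
    """

    score_threshold: float = 0.6
    marker_map: Mapping[str, Sequence[str]] = field(default_factory=dict)
    max_marker_types: int = 1
    expr_cell_frac: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0,1]")


def flag_doublet_clusters(
    table: CellTable, rule: DoubletRuleParams = DoubletRuleParams()
) -> tuple[set, CellTable]:
    """Remove whole clusters that look like doublets; returns (removed, table)."""
    if "cluster" not in table.cell_meta.columns:
        raise ValueError("cell_meta must carry a 'cluster' column")
    if "doublet_score" not in table.cell_meta.columns:
        raise ValueError("cell_meta must carry a 'doublet_score' column")

    removed: set = set()
    binar = table.counts > 0
    for cluster, idx in table.cell_meta.groupby("cluster", sort=True).indices.items():
        idx = np.asarray(idx)
        if table.cell_meta["doublet_score"].iloc[idx].mean() > rule.score_threshold:
            removed.add(cluster)
            continue
        n_types = 0
        for _type, markers in rule.marker_map.items():
            present = [m for m in markers if m in table.gene_meta.index]
            if not present:
                continue
            cols = table.gene_indexer(present)
            frac = np.asarray(binar[idx][:, cols].mean(axis=0)).ravel()
            if (frac > rule.expr_cell_frac).any():
                n_types += 1
        if n_types > rule.max_marker_types:
            removed.add(cluster)

    keep = ~table.cell_meta["cluster"].isin(removed).to_numpy()
    return removed, table.subset_cells(keep)


# --------------------------------------------------------------------------- #
# ambient contamination


@dataclass
class AmbientModel:
    """Pooled ambient profile and estimated contamination fraction."""

    ambient_profile: pd.Series  # per-gene proportion, sums to 1
    rho: float
    per_set_rho: dict[str, float]

    def __post_init__(self) -> None:
        s = float(self.ambient_profile.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"ambient profile sums to {s}, expected 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")


def estimate_contamination(
    table: CellTable,
    marker_sets: Mapping[str, Sequence[str]],
    nonexpressing: Mapping[str, set],
) -> AmbientModel:
    """Estimate the channel-level contamination fraction rho.

    For each marker set ``s`` with genes ``G_s`` and non-expressing clusters
    ``C_s``, the observed marker counts in those clusters must all be ambient:

        rho_s = sum_{c in C_s, g in G_s} x_cg
                / (sum_{c in C_s} N_c * sum_{g in G_s} b_g)

    with ``b`` the pooled expression profile. The global rho pools numerators
    and denominators over all sets and is clipped to [0, 0.5].
    """
    if table.layer != "raw":
        raise ValueError("estimate_contamination expects the raw layer")
    if "cluster" not in table.cell_meta.columns:
        raise ValueError("cell_meta must carry a 'cluster' column")

    totals = table.cell_totals().astype(float)
    grand = totals.sum()
    if grand == 0:
        raise EstimationError("count matrix is empty")
    b = np.asarray(table.counts.sum(axis=0)).ravel().astype(float) / grand

    clusters = table.cell_meta["cluster"]
    num_pool = 0.0
    den_pool = 0.0
    per_set: dict[str, float] = {}
    for name, genes in marker_sets.items():
        present = [g for g in genes if g in table.gene_meta.index]
        if not present:
            raise EstimationError(f"marker set {name!r} has no genes in the data")
        if name not in nonexpressing or not nonexpressing[name]:
            raise EstimationError(f"no non-expressing clusters declared for {name!r}")
        cols = table.gene_indexer(present)
        cells = clusters.isin(nonexpressing[name]).to_numpy()
        if not cells.any():
            raise EstimationError(f"non-expressing clusters of {name!r} hold no cells")
        num = float(table.counts[cells][:, cols].sum())
        den = float(totals[cells].sum() * b[cols].sum())
        if den == 0:
            raise EstimationError(f"zero denominator for marker set {name!r}")
        per_set[name] = num / den
        num_pool += num
        den_pool += den

    rho = float(np.clip(num_pool / den_pool, 0.0, 0.5))
    return AmbientModel(
        ambient_profile=pd.Series(b, index=table.gene_meta.index, name="b"),
        rho=rho,
        per_set_rho=per_set,
    )


def adjust_counts(table: CellTable, model: AmbientModel) -> CellTable:
    """Subtract the expected ambient counts: x' = max(0, round(x - rho N_c b)).

    Only nonzero entries can change (a zero entry stays zero), so sparsity is
    preserved and the grand total never increases.
    """
    if table.layer != "raw":
        raise ValueError("adjust_counts expects the raw layer")
    if not 0.0 <= model.rho < 1.0:
        raise ValueError("rho must be in [0, 1)")

    counts = table.counts.tocsr().astype(np.int64)
    if model.rho > 0 and counts.nnz:
        b = model.ambient_profile.reindex(table.gene_meta.index).fillna(0.0).to_numpy()
        totals = table.cell_totals().astype(float)
        coo = counts.tocoo()
        expected = model.rho * totals[coo.row] * b[coo.col]
        new = np.maximum(0, np.rint(coo.data - expected)).astype(np.int64)
        counts = sp.csr_matrix((new, (coo.row, coo.col)), shape=counts.shape)
        counts.eliminate_zeros()
    return replace(table, counts=counts, layer="adjusted")


# --------------------------------------------------------------------------- #
# normalization


def normalize_log(table: CellTable, scale: float = 1e4) -> CellTable:
    """Depth-normalize and log-transform: y = ln(1 + scale * x / N_c).

    Cells with zero total counts are dropped with a warning.
    """
    if table.layer not in ("raw", "adjusted"):
        raise ValueError("normalize_log expects a count layer (raw or adjusted)")
    totals = table.cell_totals().astype(float)
    nz = totals > 0
    if not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} zero-total cells", stacklevel=2)
        table = table.subset_cells(nz)
        totals = totals[nz]
    out = table.counts.astype(np.float64).tocsr()
    inv = sp.diags(scale / totals)
    out = inv @ out
    out.data = np.log1p(out.data)
    return replace(table, counts=out, layer="lognorm")


# --------------------------------------------------------------------------- #
# convenience pipeline


def run_qc_pipeline(
    table: CellTable,
    thr: QcThresholds = QcThresholds(),
    doublet_rule: DoubletRuleParams | None = None,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
    nonexpressing: Mapping[str, set] | None = None,
) -> tuple[CellTable, dict]:
    """Filters -> doublet-cluster rule -> ambient adjustment, with a
    telescoping report of cell counts at each step."""
    report: dict = {"n_input": table.n_cells}
    table, qc_report = filter_cells(table, thr)
    report["qc"] = qc_report
    if doublet_rule is not None:
        removed, table = flag_doublet_clusters(table, doublet_rule)
        report["doublet_clusters_removed"] = sorted(map(str, removed))
        report["n_after_doublet_rule"] = table.n_cells
    if marker_sets is not None and nonexpressing is not None:
        model = estimate_contamination(table, marker_sets, nonexpressing)
        report["rho"] = model.rho
        report["per_set_rho"] = model.per_set_rho
        table = adjust_counts(table, model)
    report["n_output"] = table.n_cells
    return table, report
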