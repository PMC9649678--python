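"""Expression-inferred copy-number profiles and malignancy calling.

The procedure follows the moving-average convention for single-cell CNV
inference from expression:

1. genes are ordered by genomic position within each chromosome;
2. log-normalized expression is centered on a reference-cell mean and
   clamped to ``[-clamp_bound, +clamp_bound]``;
3. the initial CNV value ``CNV_i(c, w)`` is the mean of the clamped relative
   expression over a sliding window of ``W`` genes (stride 1, windows never
   crossing chromosome boundaries);
4. the final value ``CNV_f = exp(CNV_i - median_w CNV_i)`` re-centers each
   cell on its own median window so that copy-neutral windows sit near 1;
5. per cell, the CNV score is ``S = sum_w CNV_f^2`` and the malignancy score
   is ``M = mean_w (CNV_f - 1)^2``;
6. a Gaussian-KDE density of M is scanned for two modes; the threshold is
   the density minimum between the two highest peaks, and cells above it
   are called malignant. Unimodal densities yield no threshold (all cells
   non-malignant, with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .containers import CellTable


@dataclass(frozen=True)
class CnvParams:
    """Windowing and clamping parameters for CNV inference."""

    window: int = 100
    clamp_bound: float = 3.0
    reference_cells: frozenset = frozenset()  # default: caller passes non-epithelial

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.clamp_bound <= 0:
            raise ValueError("clamp_bound must be positive")


@dataclass
class CnvProfile:
    """Windowed CNV_f values plus derived per-cell scores."""

    windows: pd.DataFrame  # chromosome, start index within chromosome, gene span
    cnv_f: np.ndarray  # cells x windows, positive, neutral ~ 1
    cell_ids: pd.Index
    cnv_score: np.ndarray | None = None  # S
    malignancy_score: np.ndarray | None = None  # M
    excluded_chromosomes: list = field(default_factory=list)


@dataclass
class MalignancyCall:
    threshold: float | None
    malignant: pd.Series  # bool, indexed by cell id


# --------------------------------------------------------------------------- #


def order_genes(gene_meta: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chromosome gene positional indices, ordered by start (ties by symbol).

    Genes lacking chromosome or start are excluded. Raises if nothing is
    positioned.
    """
    if not {"chromosome", "start"} <= set(gene_meta.columns):
        raise ValueError("gene_meta needs 'chromosome' and 'start' columns")
    pos = gene_meta.reset_index()
    sym_col = pos.columns[0]
    pos["_idx"] = np.arange(len(pos))
    pos = pos.dropna(subset=["chromosome", "start"])
    if pos.empty:
        raise ValueError("no genes with genomic positions")
    pos = pos.sort_values(["chromosome", "start", sym_col], kind="stable")
    return {
        str(chrom): grp["_idx"].to_numpy()
        for chrom, grp in pos.groupby("chromosome", sort=True)
    }


def relative_expression(table: CellTable, params: CnvParams) -> np.ndarray:
    """Reference-centered, clamped expression matrix (dense, cells x genes)."""
    if table.layer != "lognorm":
        raise ValueError("relative_expression expects the lognorm layer")
    ref = params.reference_cells
    if not ref:
        raise ValueError("reference_cells must be non-empty")
    ref_pos = table.cell_meta.index.get_indexer(list(ref))
    ref_pos = ref_pos[ref_pos >= 0]
    if len(ref_pos) == 0:
        raise ValueError("no reference cells found in the table")
    y = np.asarray(table.counts.todense(), dtype=np.float64)
    ref_mean = y[ref_pos].mean(axis=0)
    r = y - ref_mean
    np.clip(r, -params.clamp_bound, params.clamp_bound, out=r)
    return r


def moving_average_cnv(
    r: np.ndarray,
    gene_order: dict[str, np.ndarray],
    params: CnvParams,
    cell_ids: pd.Index | None = None,
) -> CnvProfile:
    """Sliding-window CNV_i and median-recentered CNV_f.

    Chromosomes with fewer than ``window`` positioned genes are excluded
    (and reported on the profile); an error is raised if none remain.
    """
    W = params.window
    blocks: list[np.ndarray] = []
    win_rows: list[tuple[str, int, str]] = []
    excluded: list[str] = []
    for chrom, idx in gene_order.items():
        if len(idx) < W:
            excluded.append(chrom)
            continue
        sub = r[:, idx]
        cs = np.cumsum(sub, axis=1, dtype=np.float64)
        cs = np.concatenate([np.zeros((sub.shape[0], 1)), cs], axis=1)
        means = (cs[:, W:] - cs[:, :-W]) / W  # cells x (n - W + 1)
        blocks.append(means)
        for s in range(len(idx) - W + 1):
            win_rows.append((chrom, s, f"{s}:{s + W}"))
    if not blocks:
        raise ValueError(f"no chromosome has >= {W} positioned genes")
    cnv_i = np.concatenate(blocks, axis=1)
    med = np.median(cnv_i, axis=1, keepdims=True)
    cnv_f = np.exp(cnv_i - med)
    windows = pd.DataFrame(win_rows, columns=["chromosome", "start", "span"])
    ids = cell_ids if cell_ids is not None else pd.RangeIndex(r.shape[0])
    return CnvProfile(
        windows=windows, cnv_f=cnv_f, cell_ids=pd.Index(ids), excluded_chromosomes=excluded
    )


def score_cells(profile: CnvProfile) -> tuple[np.ndarray, np.ndarray]:
    """CNV score S = sum_w CNV_f^2 and malignancy score M = mean_w (CNV_f - 1)^2."""
    f = profile.cnv_f
    S = np.sum(f**2, axis=1)
    M = np.mean((f - 1.0) ** 2, axis=1)
    profile.cnv_score = S
    profile.malignancy_score = M
    return S, M


def bimodal_threshold(
    m_values: np.ndarray,
    cell_ids: pd.Index | None = None,
    min_n: int = 20,
    prominence_frac: float = 0.05,
    grid_size: int = 512,
) -> MalignancyCall:
    """Valley of the KDE (Silverman bandwidth) between the two highest modes.

    Modes need a prominence of at least ``prominence_frac`` of the peak
    density; with fewer than two such modes the call is a no-threshold
    fallback (everything non-malignant) with a warning.
    """
    m = np.asarray(m_values, dtype=np.float64)
    if m.size < min_n:
        raise ValueError(f"need at least {min_n} malignancy scores, got {m.size}")
    ids = pd.Index(cell_ids) if cell_ids is not None else pd.RangeIndex(m.size)

    kde = gaussian_kde(m, bw_method="silverman")
    bw = kde.factor * m.std(ddof=1)
    grid = np.linspace(m.min() - 3 * bw, m.max() + 3 * bw, grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(peaks) < 2:
        warnings.warn("malignancy score density is unimodal; no threshold", stacklevel=2)
        return MalignancyCall(
            threshold=None, malignant=pd.Series(False, index=ids, name="malignant")
        )
    top2 = sorted(peaks[np.argsort(dens[peaks])[-2:]])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    threshold = float(grid[valley])
    return MalignancyCall(
        threshold=threshold,
        malignant=pd.Series(m > threshold, index=ids, name="malignant"),
    )


def cnv_cluster(profile: CnvProfile, k: int) -> pd.Series:
    """Ward hierarchical clustering of CNV_f vectors cut at ``k`` clusters.

    Meant for malignant cells only; labels are deterministic given input
    order. Identical profiles yield an arbitrary but deterministic cut,
    flagged with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = profile.cnv_f.shape[0]
    if n < k:
        raise ValueError(f"cannot cut {n} cells into {k} clusters")
    if np.allclose(profile.cnv_f, profile.cnv_f[0]):
        warnings.warn("all CNV profiles identical; clustering is degenerate", stacklevel=2)
    Z = linkage(profile.cnv_f, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=profile.cell_ids, name="cnv_clone")


# --------------------------------------------------------------------------- #


def call_malignant(
    table: CellTable,
    params: CnvParams | None = None,
    reference_clusters: set | None = None,
) -> tuple[CnvProfile, MalignancyCall]:
    """End-to-end CNV malignancy calling on a lognorm table.

    ``reference_clusters`` names the copy-neutral (non-epithelial) clusters
    used for centering; all cells are scored.
    """
    if reference_clusters is None and (params is None or not params.reference_cells):
        raise ValueError("provide reference_clusters or CnvParams.reference_cells")
    if params is None:
        params = CnvParams()
    if not params.reference_cells:
        ref_ids = table.cell_meta.index[
            table.cell_meta["cluster"].isin(reference_clusters)
        ]
        params = CnvParams(
            window=params.window,
            clamp_bound=params.clamp_bound,
            reference_cells=frozenset(ref_ids),
        )
    order = order_genes(table.gene_meta)
    r = relative_expression(table, params)
    profile = moving_average_cnv(r, order, params, cell_ids=table.cell_meta.index)
    _, m = score_cells(profile)
    call = bimodal_threshold(m, cell_ids=profile.cell_ids)
    return profile, call
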