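"""Permutation-based ligand-receptor interaction testing between clusters.

The test follows the CellPhoneDB recipe: clusters are downsampled to at
most ``downsample_n`` cells, a pair's strength between an ordered cluster
pair (A, B) is the mean of the ligand's average expression in A and the
receptor's average expression in B, pairs whose ligand (receptor) is
expressed by no more than ``min_expr_frac`` of A's (B's) cells are
filtered, and significance comes from globally permuting cluster labels
``n_perm`` times: p = #(permuted strength >= observed) / n_perm.

Multi-subunit complexes score as the minimum expression over subunits
(limiting-subunit convention); "expressed" means complex value > 0 on the
log-normalized layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CellTable
from .tcr import differential_expression


@dataclass(frozen=True)
class InteractionParams:
    downsample_n: int = 1000
    n_perm: int = 1000
    min_expr_frac: float = 0.30
    p_cut: float = 0.05
    seed: int = 0
    add_one: bool = False  # p = (count + 1) / (n_perm + 1) variant

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.min_expr_frac < 1.0:
            raise ValueError("min_expr_frac must be in (0, 1)")


@dataclass
class LRPairList:
    """Resolved ligand-receptor pairs; unresolvable ones are dropped."""

    pairs: pd.DataFrame  # pair_id, ligand (tuple), receptor (tuple)
    dropped: list[str] = field(default_factory=list)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, gene_symbols) -> "LRPairList":
        """Parse a pair table with ';'-separated subunit columns."""
        known = set(gene_symbols)
        rows, dropped = [], []
        for _, r in frame.iterrows():
            lig = tuple(str(r["ligand_subunits"]).split(";"))
            rec = tuple(str(r["receptor_subunits"]).split(";"))
            if all(s in known for s in (*lig, *rec)):
                rows.append((r["pair_id"], lig, rec))
            else:
                dropped.append(r["pair_id"])
        return cls(
            pairs=pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor"]),
            dropped=dropped,
        )


# --------------------------------------------------------------------------- #


def downsample_by_type(table: CellTable, params: InteractionParams) -> CellTable:
    """At most ``downsample_n`` cells per cluster, sampled without replacement.

    Deterministic given ``params.seed``; original cell order is preserved.
    """
    if "cluster" not in table.cell_meta.columns:
        raise ValueError("cell_meta must carry a 'cluster' column")
    rng = np.random.default_rng(params.seed)
    keep: list[np.ndarray] = []
    for _, idx in table.cell_meta.groupby("cluster", sort=True).indices.items():
        idx = np.asarray(idx)
        if len(idx) > params.downsample_n:
            idx = rng.choice(idx, size=params.downsample_n, replace=False)
        keep.append(idx)
    pos = np.sort(np.concatenate(keep))
    mask = np.zeros(table.n_cells, dtype=bool)
    mask[pos] = True
    return table.subset_cells(mask)


def complex_expression(table: CellTable, subunits: Sequence[str]) -> np.ndarray:
    """Per-cell complex expression: minimum over subunit genes."""
    if table.layer != "lognorm":
        raise ValueError("complex_expression expects the lognorm layer")
    cols = table.gene_indexer(subunits)
    vals = np.asarray(table.counts[:, cols].todense())
    return vals.min(axis=1)


def _complex_matrix(table: CellTable, complexes: list[tuple[str, ...]]) -> np.ndarray:
    out = np.empty((table.n_cells, len(complexes)), dtype=np.float64)
    for j, subunits in enumerate(complexes):
        out[:, j] = complex_expression(table, subunits)
    return out


def interaction_strength(
    table: CellTable, pairs: LRPairList, params: InteractionParams = InteractionParams()
) -> pd.DataFrame:
    """Observed strengths and expressing fractions for every ordered cluster
    pair and every LR pair.

    strength = (mean ligand expression in source + mean receptor expression
    in target) / 2. A record passes the fraction filter when the ligand is
    expressed (> 0) by more than ``min_expr_frac`` of source cells AND the
    receptor by more than ``min_expr_frac`` of target cells; failing records
    keep their strength but are marked filtered.
    """
    if table.layer != "lognorm":
        raise ValueError("interaction_strength expects the lognorm layer")
    clusters = table.cell_meta["cluster"]
    labels = sorted(clusters.unique())
    complexes = sorted(
        {c for col in ("ligand", "receptor") for c in pairs.pairs[col]}
    )
    cidx = {c: j for j, c in enumerate(complexes)}
    V = _complex_matrix(table, complexes)

    means = np.zeros((len(labels), len(complexes)))
    fracs = np.zeros_like(means)
    for i, lab in enumerate(labels):
        rows = (clusters == lab).to_numpy()
        if rows.any():
            means[i] = V[rows].mean(axis=0)
            fracs[i] = (V[rows] > 0).mean(axis=0)

    records = []
    for ai, a in enumerate(labels):
        for bi, b in enumerate(labels):
            for _, pr in pairs.pairs.iterrows():
                lj, rj = cidx[pr["ligand"]], cidx[pr["receptor"]]
                strength = 0.5 * (means[ai, lj] + means[bi, rj])
                passed = (
                    fracs[ai, lj] > params.min_expr_frac
                    and fracs[bi, rj] > params.min_expr_frac
                )
                records.append(
                    (a, b, pr["pair_id"], strength, fracs[ai, lj], fracs[bi, rj], passed)
                )
    return pd.DataFrame(
        records,
        columns=[
            "source",
            "target",
            "pair_id",
            "strength",
            "frac_source",
            "frac_target",
            "passed_fraction",
        ],
    )


def permutation_pvalues(
    table: CellTable,
    pairs: LRPairList,
    params: InteractionParams = InteractionParams(),
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation p-values for the interaction records.

    Cluster labels are permuted globally across the (downsampled) table per
    iteration; p = #(permuted strength >= observed) / n_perm (or the
    +1-corrected variant when ``params.add_one``). kept = p < p_cut AND the
    fraction filters passed. Deterministic given ``params.seed``.
    """
    if records is None:
        records = interaction_strength(table, pairs, params)
    clusters = table.cell_meta["cluster"]
    labels = sorted(clusters.unique())
    lab_pos = {lab: i for i, lab in enumerate(labels)}
    lab_vec = clusters.map(lab_pos).to_numpy()

    complexes = sorted(
        {c for col in ("ligand", "receptor") for c in pairs.pairs[col]}
    )
    cidx = {c: j for j, c in enumerate(complexes)}
    V = _complex_matrix(table, complexes)
    pair_cols = {
        pr["pair_id"]: (cidx[pr["ligand"]], cidx[pr["receptor"]])
        for _, pr in pairs.pairs.iterrows()
    }

    a_idx = records["source"].map(lab_pos).to_numpy()
    b_idx = records["target"].map(lab_pos).to_numpy()
    l_col = records["pair_id"].map(lambda p: pair_cols[p][0]).to_numpy()
    r_col = records["pair_id"].map(lambda p: pair_cols[p][1]).to_numpy()
    observed = records["strength"].to_numpy()

    K = len(labels)
    sizes = np.bincount(lab_vec, minlength=K).astype(float)
    rng = np.random.default_rng(params.seed)
    exceed = np.zeros(len(records), dtype=np.int64)
    perm = lab_vec.copy()
    for _ in range(params.n_perm):
        rng.shuffle(perm)
        sums = np.zeros((K, V.shape[1]))
        np.add.at(sums, perm, V)
        m = sums / sizes[:, None]
        strength = 0.5 * (m[a_idx, l_col] + m[b_idx, r_col])
        exceed += strength >= observed

    if params.add_one:
        p = (exceed + 1) / (params.n_perm + 1)
    else:
        p = exceed / params.n_perm
    out = records.copy()
    out["p"] = p
    out["kept"] = (p < params.p_cut) & out["passed_fraction"]
    return out


# --------------------------------------------------------------------------- #
# DEG-based pre-filtering


def deg_prefilter(
    table: CellTable,
    clusters_of_interest: Sequence,
    lfc: float = 0.5,
    min_pct: float = 0.25,
) -> set[str]:
    """One-vs-rest marker genes for the focal clusters.

    Per focal cluster, a gene is retained when its log2 fold change over the
    rest exceeds ``lfc`` and more than ``min_pct`` of the cluster's cells
    express it (Wilcoxon p is computed alongside but the retention rule is
    the printed fold-change/fraction criterion). The union over the focal
    clusters is returned; restrict interaction records to pairs whose
    ligand or receptor intersects this set.
    """
    if table.layer != "lognorm":
        raise ValueError("deg_prefilter expects the lognorm layer")
    clusters = table.cell_meta["cluster"]
    genes: set[str] = set()
    for focal in clusters_of_interest:
        in_focal = (clusters == focal).to_numpy()
        if not in_focal.any():
            raise ValueError(f"cluster {focal!r} not present")
        de = differential_expression(
            table,
            table.cell_meta.index[in_focal],
            table.cell_meta.index[~in_focal],
            lfc_cut=lfc,
        )
        pct = np.asarray((table.counts[in_focal] > 0).mean(axis=0)).ravel()
        keep = (de["log2fc"].to_numpy() > lfc) & (pct > min_pct)
        genes |= set(de.loc[keep, "gene"])
    return genes


def restrict_to_deg(records: pd.DataFrame, pairs: LRPairList, genes: set[str]) -> pd.DataFrame:
    """Keep interaction records whose ligand or receptor touches ``genes``."""
    touch = {
        pr["pair_id"]
        for _, pr in pairs.pairs.iterrows()
        if set(pr["ligand"]) & genes or set(pr["receptor"]) & genes
    }
    return records[records["pair_id"].isin(touch)].reset_index(drop=True)
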