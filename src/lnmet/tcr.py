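"""TCR chain pairing, clonotypes, STARTRAC clonality indices, and matched
T cells across paired tissues.

Cells are first classified by their productive TRA/TRB chain multiset into
seven pairing categories; only single-pair cells enter clonotype building.
A clonotype is the set of a patient's cells sharing identical TRA and TRB
CDR3 nucleotide sequences. Two repertoire indices quantify clonal behaviour
within a grouping:

* STARTRAC-expansion = 1 - normalized Shannon entropy of clonotype
  frequencies (0 = fully polyclonal, 1 = monoclonal);
* STARTRAC-transition = clone-size-weighted mean of per-clonotype
  normalized entropies across the clusters of a (patient, tissue) stratum.

Matched T (MT) cells are cells whose clonotype has members in both tissues
of the same patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import CellTable

PAIRING_CATEGORIES = (
    "single_pair",
    "orphan_alpha",
    "orphan_beta",
    "extra_alpha",
    "extra_beta",
    "two_full_chains",
    "multichain",
)


def classify_pairing(n_alpha: int, n_beta: int) -> str | None:
    """Map a productive (TRA, TRB) chain count pair to a pairing category.

    ``None`` means the cell has no productive chains and is excluded.
    Counts above two of any chain are multichain; a doubled chain without a
    full pair counts as the corresponding "extra" category.
    """
    if n_alpha == 0 and n_beta == 0:
        return None
    if n_alpha > 2 or n_beta > 2:
        return "multichain"
    return {
        (1, 1): "single_pair",
        (1, 0): "orphan_alpha",
        (0, 1): "orphan_beta",
        (2, 1): "extra_alpha",
        (2, 0): "extra_alpha",
        (1, 2): "extra_beta",
        (0, 2): "extra_beta",
        (2, 2): "two_full_chains",
    }[(n_alpha, n_beta)]


def _normalize_barcode(barcodes: pd.Series) -> pd.Series:
    return barcodes.str.replace(r"-\d+$", "", regex=True)


def summarize_pairing(contigs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell pairing categories from a 10x-style contig table.

    Expects columns barcode, chain in {TRA, TRB}, cdr3, cdr3_nt, productive.
    Non-productive contigs are ignored. Returns one row per TCR-bearing cell:
    cell_id, category, tra_nt, trb_nt (chain CDR3s only for single-pair cells).
    """
    df = contigs.copy()
    prod = df["productive"]
    if prod.dtype == object:
        prod = prod.astype(str).str.lower().isin(("true", "t", "1", "yes"))
    df = df[prod.astype(bool) & df["chain"].isin(("TRA", "TRB"))]
    df["cell_id"] = _normalize_barcode(df["barcode"].astype(str))

    rows = []
    for cell, grp in df.groupby("cell_id", sort=True):
        tra = grp[grp["chain"] == "TRA"]
        trb = grp[grp["chain"] == "TRB"]
        cat = classify_pairing(len(tra), len(trb))
        if cat is None:
            continue
        tra_nt = tra["cdr3_nt"].iloc[0] if cat == "single_pair" else pd.NA
        trb_nt = trb["cdr3_nt"].iloc[0] if cat == "single_pair" else pd.NA
        rows.append((cell, cat, tra_nt, trb_nt))
    return pd.DataFrame(rows, columns=["cell_id", "category", "tra_nt", "trb_nt"])


# --------------------------------------------------------------------------- #
# clonotypes


def build_clonotypes(
    contigs: pd.DataFrame,
    cell_meta: pd.DataFrame,
    chain_match: str = "both",
) -> pd.DataFrame:
    """Clonotype assignments for single-pair cells with patient/tissue context.

    The clonotype key is (patient, TRA cdr3_nt, TRB cdr3_nt) by exact string
    match; ``chain_match="any"`` switches to the looser reading where either
    chain alone defines identity (cells sharing a TRA *or* a TRB are merged
    by union-find within a patient).

    Returns one row per single-pair cell joined to ``cell_meta``:
    cell_id, patient, tissue, cluster (if present), clonotype_id.
    """
    pairing = summarize_pairing(contigs)
    sp_cells = pairing[pairing["category"] == "single_pair"].copy()
    sp_cells = sp_cells[sp_cells["cell_id"].isin(cell_meta.index)]
    ctx_cols = [c for c in ("patient", "tissue", "cluster") if c in cell_meta.columns]
    sp_cells = sp_cells.join(cell_meta[ctx_cols], on="cell_id")

    if chain_match == "both":
        key = (
            sp_cells["patient"].astype(str)
            + "|"
            + sp_cells["tra_nt"].astype(str)
            + "|"
            + sp_cells["trb_nt"].astype(str)
        )
        codes, _ = pd.factorize(key, sort=True)
        sp_cells["clonotype_id"] = [f"ct{c:05d}" for c in codes]
    elif chain_match == "any":
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for _, row in sp_cells.iterrows():
            a = f"{row['patient']}|A|{row['tra_nt']}"
            b = f"{row['patient']}|B|{row['trb_nt']}"
            parent[find(a)] = find(b)
        roots = [
            find(f"{r['patient']}|A|{r['tra_nt']}") for _, r in sp_cells.iterrows()
        ]
        codes, _ = pd.factorize(pd.Series(roots), sort=True)
        sp_cells["clonotype_id"] = [f"ct{c:05d}" for c in codes]
    else:
        raise ValueError("chain_match must be 'both' or 'any'")

    return sp_cells[["cell_id", *ctx_cols, "clonotype_id", "tra_nt", "trb_nt"]].reset_index(
        drop=True
    )


def clonal_size_fractions(
    clonotypes: pd.DataFrame, grouping: Sequence[str] = ("patient", "tissue")
) -> pd.DataFrame:
    """Fraction of cells in clonotypes of size 1, 2 and >= 3, per group.

    Sizes are computed within each group; fractions are cell-weighted and
    sum to 1. Empty groups cannot occur (groups come from the data).
    """
    grouping = list(grouping)
    out = []
    for keys, grp in clonotypes.groupby(grouping, sort=True):
        sizes = grp.groupby("clonotype_id").size()
        per_cell = grp["clonotype_id"].map(sizes)
        n = len(grp)
        out.append(
            (*np.atleast_1d(keys), n,
             float((per_cell == 1).sum() / n),
             float((per_cell == 2).sum() / n),
             float((per_cell >= 3).sum() / n))
        )
    return pd.DataFrame(
        out, columns=[*grouping, "n_cells", "frac_size1", "frac_size2", "frac_size3plus"]
    )


# --------------------------------------------------------------------------- #
# STARTRAC indices


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def startrac_expansion(
    clonotypes: pd.DataFrame,
    grouping: Sequence[str] = ("patient", "tissue", "cluster"),
) -> pd.DataFrame:
    """STARTRAC-expansion = 1 - H(p)/ln(n_clonotypes) per group.

    Groups with fewer than 2 cells are undefined (NaN); monoclonal groups
    with >= 2 cells score 1 (the vanishing-evenness limit).
    """
    grouping = list(grouping)
    rows = []
    for keys, grp in clonotypes.groupby(grouping, sort=True):
        n = len(grp)
        if n < 2:
            exp = np.nan
        else:
            counts = grp.groupby("clonotype_id").size().to_numpy(float)
            if len(counts) == 1:
                exp = 1.0
            else:
                evenness = _entropy(counts / counts.sum()) / np.log(len(counts))
                exp = 1.0 - evenness
        rows.append((*np.atleast_1d(keys), n, exp))
    return pd.DataFrame(rows, columns=[*grouping, "n_cells", "expansion"])


def startrac_transition(
    clonotypes: pd.DataFrame,
    grouping: Sequence[str] = ("patient", "tissue"),
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """Cluster-level STARTRAC-transition within each stratum.

    With K clusters in a (patient, tissue) stratum, each clonotype t with
    cluster distribution q gets trans(t) = H(q)/ln(K) if it spans >= 2
    clusters, else 0. The index of cluster k averages trans(t) over the
    clonotypes with cells in k, weighted by the clone's cell count within k.
    Strata with K < 2 are undefined (skipped with an empty result for them).
    """
    grouping = list(grouping)
    rows = []
    for keys, grp in clonotypes.groupby(grouping, sort=True):
        K = grp[cluster_col].nunique()
        if K < 2:
            continue
        trans: dict[str, float] = {}
        for ct, sub in grp.groupby("clonotype_id"):
            q = sub[cluster_col].value_counts(normalize=True).to_numpy()
            trans[ct] = _entropy(q) / np.log(K) if len(q) >= 2 else 0.0
        for cluster, sub in grp.groupby(cluster_col, sort=True):
            w_in_k = sub.groupby("clonotype_id").size()
            w = w_in_k.to_numpy(float)
            t = np.array([trans[c] for c in w_in_k.index])
            rows.append((*np.atleast_1d(keys), cluster, float((w * t).sum() / w.sum())))
    return pd.DataFrame(rows, columns=[*grouping, cluster_col, "transition"])


# --------------------------------------------------------------------------- #
# matched T cells


@dataclass
class MatchedTSet:
    matched: pd.Series  # bool per cell (index: cell_id)
    fractions: pd.DataFrame  # per (patient, tissue): matched fraction
    excluded_patients: list[str]


def find_matched_t(clonotypes: pd.DataFrame) -> MatchedTSet:
    """Flag cells whose clonotype spans both tissues of the same patient.

    Patients with only one tissue in the table are excluded and reported.
    """
    tissues_per_patient = clonotypes.groupby("patient")["tissue"].nunique()
    excluded = sorted(tissues_per_patient.index[tissues_per_patient < 2].astype(str))
    usable = clonotypes[~clonotypes["patient"].isin(excluded)]

    span = usable.groupby("clonotype_id")["tissue"].nunique()
    matched_cts = set(span.index[span >= 2])
    matched = usable["clonotype_id"].isin(matched_cts)
    matched_cells = pd.Series(
        matched.to_numpy(), index=pd.Index(usable["cell_id"]), name="matched"
    )

    frac = (
        usable.assign(matched=matched.to_numpy())
        .groupby(["patient", "tissue"], sort=True)["matched"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "matched_fraction", "size": "n_cells"})
        .reset_index()
    )
    return MatchedTSet(matched=matched_cells, fractions=frac, excluded_patients=excluded)


# --------------------------------------------------------------------------- #
# differential expression


def differential_expression(
    table: CellTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_cut: float = 0.05,
    lfc_cut: float = 0.25,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two cell groups.

    Per gene: rank-sum p on the lognorm layer, Benjamini-Hochberg q, and
    log2 fold change of the de-logged (expm1) group means with pseudocount
    1e-9, so a planted k-fold count difference reports ~log2(k).
    ``significant`` requires q < p_cut and |log2FC| >= lfc_cut. Both groups
    need >= 3 cells.
    """
    if table.layer != "lognorm":
        raise ValueError("differential_expression expects the lognorm layer")
    ia = table.cell_meta.index.get_indexer(list(group_a))
    ib = table.cell_meta.index.get_indexer(list(group_b))
    if (ia < 0).any() or (ib < 0).any():
        raise KeyError("unknown cell ids in DE groups")
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("both groups need at least 3 cells")

    xa = np.asarray(table.counts[ia].todense())
    xb = np.asarray(table.counts[ib].todense())
    with np.errstate(invalid="ignore"):
        res = mannwhitneyu(xa, xb, axis=0, alternative="two-sided")
    p = np.nan_to_num(res.pvalue, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    eps = 1e-9
    lfc = np.log2(
        (np.expm1(xa).mean(axis=0) + eps) / (np.expm1(xb).mean(axis=0) + eps)
    )
    out = pd.DataFrame(
        {
            "gene": table.gene_meta.index,
            "mean_a": xa.mean(axis=0),
            "mean_b": xb.mean(axis=0),
            "log2fc": lfc,
            "p": p,
            "q": q,
        }
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["significant"] = (out["q"] < p_cut) & (out["log2fc"].abs() >= lfc_cut)
    return out
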