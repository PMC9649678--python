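"""Cell-type composition statistics and gene-signature scoring.

Composition uses sample-size-scaled proportions: the count of type t in
category k is first divided by the category's total cell count
(``scaled = n_tk / N_k``), and the share of category k within type t is the
scaled value renormalized across categories. This removes the dominance of
large samples when comparing, e.g., PT against LNMT.

Signature scores are plain means of member-gene expression; units are
stratified into high/low groups by the 55th/45th percentiles (linear
interpolation), leaving the middle band excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .containers import CellTable


@dataclass(frozen=True)
class SignatureDef:
    name: str
    genes: tuple[str, ...]

    def resolve(self, symbols) -> tuple[list[str], list[str]]:
        known = set(symbols)
        found = [g for g in self.genes if g in known]
        missing = [g for g in self.genes if g not in known]
        if not found:
            raise ValueError(f"signature {self.name!r}: no resolvable genes")
        return found, missing


# --------------------------------------------------------------------------- #
# composition


def scaled_composition(
    cell_meta: pd.DataFrame, type_col: str, category_col: str
) -> pd.DataFrame:
    """Sample-size-scaled composition table.

    Rows are (type, category) with raw count, ``scaled = n_tk / N_k`` and
    ``share`` = scaled renormalized within the type (shares sum to 1 across
    categories for each type).
    """
    for col in (type_col, category_col):
        if col not in cell_meta.columns:
            raise ValueError(f"missing column {col!r}")
    counts = (
        cell_meta.groupby([type_col, category_col], sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    cat_totals = cell_meta.groupby(category_col, observed=True).size()
    if (cat_totals == 0).any():
        raise ValueError("empty category")
    counts["scaled"] = counts["count"] / counts[category_col].map(cat_totals).to_numpy()
    denom = counts.groupby(type_col, observed=True)["scaled"].transform("sum")
    counts["share"] = counts["scaled"] / denom
    return counts


def per_sample_fraction_test(
    cell_meta: pd.DataFrame,
    type_col: str,
    sample_col: str,
    category_col: str,
    paired_by: str | None = None,
) -> pd.DataFrame:
    """Per-type Wilcoxon test of per-sample fractions across two categories.

    Each sample's fraction of type t is ``n_ts / N_s``. The default is the
    unpaired rank-sum test; ``paired_by`` (e.g., "patient") switches to the
    signed-rank test on patient-matched sample pairs. Types with fewer than
    3 samples per category are reported with NaN p.
    """
    cats = sorted(cell_meta[category_col].unique())
    if len(cats) != 2:
        raise ValueError(f"need exactly 2 categories, got {cats}")
    totals = cell_meta.groupby(sample_col, observed=True).size()
    frac = (
        cell_meta.groupby([sample_col, type_col], sort=True, observed=True)
        .size()
        .unstack(fill_value=0)
        .div(totals, axis=0)
    )
    sample_cat = cell_meta.groupby(sample_col, observed=True)[category_col].first()
    sample_pat = (
        cell_meta.groupby(sample_col, observed=True)[paired_by].first()
        if paired_by
        else None
    )

    rows = []
    for t in frac.columns:
        xs = {c: frac.loc[sample_cat == c, t] for c in cats}
        if min(len(xs[cats[0]]), len(xs[cats[1]])) < 3:
            rows.append((t, xs[cats[0]].mean(), xs[cats[1]].mean(), np.nan))
            continue
        if paired_by:
            a = xs[cats[0]].groupby(sample_pat).mean()
            b = xs[cats[1]].groupby(sample_pat).mean()
            common = a.index.intersection(b.index)
            diff = a.loc[common] - b.loc[common]
            p = 1.0 if (diff == 0).all() else float(
                wilcoxon(a.loc[common], b.loc[common]).pvalue
            )
        else:
            if xs[cats[0]].nunique() == 1 and xs[cats[1]].nunique() == 1 and (
                xs[cats[0]].iloc[0] == xs[cats[1]].iloc[0]
            ):
                p = 1.0
            else:
                p = float(
                    mannwhitneyu(xs[cats[0]], xs[cats[1]], alternative="two-sided").pvalue
                )
        rows.append((t, xs[cats[0]].mean(), xs[cats[1]].mean(), p))
    return pd.DataFrame(
        rows, columns=[type_col, f"mean_{cats[0]}", f"mean_{cats[1]}", "p"]
    )


# --------------------------------------------------------------------------- #
# signatures


def signature_score(data: CellTable | pd.DataFrame, sig: SignatureDef) -> pd.Series:
    """Mean expression of the signature's resolvable genes per unit.

    ``data`` is either a lognorm :class:`CellTable` (per-cell scores) or a
    units x genes DataFrame of log expression (per-sample scores, e.g.
    bulk cohorts).
    """
    if isinstance(data, CellTable):
        if data.layer != "lognorm":
            raise ValueError("signature_score expects the lognorm layer")
        found, _ = sig.resolve(data.gene_meta.index)
        cols = data.gene_indexer(found)
        vals = np.asarray(data.counts[:, cols].todense()).mean(axis=1)
        return pd.Series(vals, index=data.cell_meta.index, name=sig.name)
    found, _ = sig.resolve(data.columns)
    return data[found].mean(axis=1).rename(sig.name)


def signature_ratio(
    data: CellTable | pd.DataFrame, sig_a: SignatureDef, sig_b: SignatureDef
) -> pd.Series:
    """Per-unit score ratio A/B; units with zero denominator are NaN."""
    a = signature_score(data, sig_a)
    b = signature_score(data, sig_b)
    if (b == 0).all():
        raise ValueError("all denominator scores are zero")
    ratio = a / b.where(b != 0)
    return ratio.rename(f"{sig_a.name}/{sig_b.name}")


def quantile_groups(
    scores: pd.Series | Sequence[float], hi: float = 0.55, lo: float = 0.45
) -> pd.Series:
    """high / low / excluded labels by the ``hi`` and ``lo`` quantiles.

    high = score > Q(hi); low = score < Q(lo); the rest excluded. Quantiles
    use linear interpolation. Constant scores exclude everything, with a
    warning; needs at least 10 units.
    """
    s = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    if len(s) < 10:
        raise ValueError("need at least 10 units for quantile grouping")
    q_hi = float(np.quantile(s.to_numpy(float), hi))
    q_lo = float(np.quantile(s.to_numpy(float), lo))
    labels = pd.Series("excluded", index=s.index, name="group")
    labels[s > q_hi] = "high"
    labels[s < q_lo] = "low"
    if s.nunique() == 1:
        warnings.warn("constant scores: all units excluded", stacklevel=2)
        labels[:] = "excluded"
    return labels
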