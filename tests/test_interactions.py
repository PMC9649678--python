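"""Downsampling, complex expression, interaction strength, permutation
p-values (with exhaustive oracle), DEG pre-filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lnmet import (
    InteractionParams,
    LRPairList,
    complex_expression,
    deg_prefilter,
    downsample_by_type,
    interaction_strength,
    normalize_log,
    permutation_pvalues,
    restrict_to_deg,
)

from conftest import make_table


def _pairs(rows):
    frame = pd.DataFrame(
        rows, columns=["pair_id", "ligand_subunits", "receptor_subunits"]
    )
    return frame


# --------------------------------------------------------------------------- #
# downsampling


def test_small_cluster_fully_retained_large_cluster_capped():
    n = 1500
    t = make_table(
        np.ones((n, 2), dtype=int), clusters=[0] * 500 + [1] * 1000
    )
    params = InteractionParams(downsample_n=700, seed=3)
    out = downsample_by_type(t, params)
    sizes = out.cell_meta["cluster"].value_counts()
    assert sizes[0] == 500 and sizes[1] == 700


def test_downsampling_deterministic_given_seed():
    t = make_table(np.ones((100, 2), dtype=int), clusters=[0] * 100)
    params = InteractionParams(downsample_n=30, seed=9)
    a = downsample_by_type(t, params)
    b = downsample_by_type(t, params)
    assert a.cell_meta.index.equals(b.cell_meta.index)


# --------------------------------------------------------------------------- #
# complexes


def test_single_subunit_is_identity_and_min_rule():
    y = np.array([[2.0, 0.0], [1.0, 3.0]])
    t = make_table(y, layer="lognorm")
    assert np.allclose(complex_expression(t, ["g0"]), y[:, 0])
    assert np.allclose(complex_expression(t, ["g0", "g1"]), [0.0, 1.0])


def test_complex_monotone_in_subunits():
    y = np.array([[1.0, 2.0]])
    t = make_table(y, layer="lognorm")
    lo = complex_expression(t, ["g0", "g1"])[0]
    y2 = y.copy()
    y2[0, 0] = 1.5
    hi = complex_expression(make_table(y2, layer="lognorm"), ["g0", "g1"])[0]
    assert hi >= lo


# --------------------------------------------------------------------------- #
# strength and fraction filter


def test_strength_on_constant_fixture_and_fraction_filter():
    # cluster A: ligand g0 = 2.0 everywhere; cluster B: receptor g1 = 4.0
    y = np.zeros((8, 3))
    y[:4, 0] = 2.0
    y[4:, 1] = 4.0
    y[:, 2] = 1.0
    t = make_table(y, clusters=[0] * 4 + [1] * 4, layer="lognorm")
    pairs = LRPairList.from_frame(_pairs([("p1", "g0", "g1")]), t.gene_meta.index)
    rec = interaction_strength(t, pairs, InteractionParams())
    row = rec[(rec.source == 0) & (rec.target == 1)].iloc[0]
    assert row["strength"] == pytest.approx(3.0)
    assert row["passed_fraction"]
    # reverse orientation fails the 30% filter (g0 absent in B, g1 absent in A)
    rev = rec[(rec.source == 1) & (rec.target == 0)].iloc[0]
    assert not rev["passed_fraction"]


def test_ligand_expressed_by_quarter_of_cells_is_filtered():
    y = np.zeros((8, 2))
    y[0, 0] = 5.0  # 25% of cluster A expresses the ligand -> not > 30%
    y[4:, 1] = 1.0
    t = make_table(y, clusters=[0] * 4 + [1] * 4, layer="lognorm")
    pairs = LRPairList.from_frame(_pairs([("p1", "g0", "g1")]), t.gene_meta.index)
    rec = interaction_strength(t, pairs, InteractionParams(min_expr_frac=0.30))
    assert not rec[(rec.source == 0) & (rec.target == 1)]["passed_fraction"].iloc[0]


def test_unresolvable_pair_dropped_with_report():
    t = make_table(np.ones((2, 2)), layer="lognorm")
    pairs = LRPairList.from_frame(
        _pairs([("ok", "g0", "g1"), ("bad", "g0", "missing")]), t.gene_meta.index
    )
    assert list(pairs.pairs["pair_id"]) == ["ok"]
    assert pairs.dropped == ["bad"]


# --------------------------------------------------------------------------- #
# permutation p-values


def test_identical_expression_gives_p_one():
    y = np.ones((10, 2))
    t = make_table(y, clusters=[0] * 5 + [1] * 5, layer="lognorm")
    pairs = LRPairList.from_frame(_pairs([("p1", "g0", "g1")]), t.gene_meta.index)
    rec = permutation_pvalues(t, pairs, InteractionParams(n_perm=200, seed=0))
    assert (rec["p"] == 1.0).all()


def test_planted_disjoint_interaction_detected():
    rng = np.random.default_rng(0)
    n, k = 20, 8  # 8 clusters of 20 cells
    y = rng.normal(0.1, 0.02, size=(n * k, 3)).clip(min=0)
    clusters = np.repeat(np.arange(k), n)
    y[clusters == 0, 0] = 5.0  # ligand only in cluster 0
    y[clusters == 1, 1] = 5.0  # receptor only in cluster 1
    t = make_table(y, clusters=clusters, layer="lognorm")
    pairs = LRPairList.from_frame(_pairs([("p1", "g0", "g1")]), t.gene_meta.index)
    rec = permutation_pvalues(t, pairs, InteractionParams(n_perm=1000, seed=1))
    hit = rec[(rec.source == 0) & (rec.target == 1)].iloc[0]
    assert hit["p"] <= 0.001
    assert hit["kept"]


def exhaustive_pvalue(values_l, values_r, labels, obs):
    """Exact p over all distinct label assignments of a tiny instance."""
    n = len(labels)
    n_a = labels.count(0)
    idx = range(n)
    count = 0
    total = 0
    for a_set in itertools.combinations(idx, n_a):
        in_a = [i in a_set for i in idx]
        mean_l_a = np.mean([values_l[i] for i in idx if in_a[i]])
        mean_r_b = np.mean([values_r[i] for i in idx if not in_a[i]])
        s = 0.5 * (mean_l_a + mean_r_b)
        total += 1
        if s >= obs - 1e-12:
            count += 1
    return count / total


def test_monte_carlo_p_matches_exhaustive_oracle():
    """6 cells, 2 clusters: MC p within 3 binomial SEs of the exact p."""
    y = np.array(
        [[3.0, 0.0], [2.0, 0.1], [2.5, 0.0], [0.0, 2.0], [0.1, 3.0], [0.0, 2.5]]
    )
    labels = [0, 0, 0, 1, 1, 1]
    t = make_table(y, clusters=labels, layer="lognorm")
    pairs = LRPairList.from_frame(_pairs([("p1", "g0", "g1")]), t.gene_meta.index)
    n_perm = 1000
    rec = permutation_pvalues(t, pairs, InteractionParams(n_perm=n_perm, seed=7))
    row = rec[(rec.source == 0) & (rec.target == 1)].iloc[0]
    exact = exhaustive_pvalue(y[:, 0], y[:, 1], labels, row["strength"])
    se = math.sqrt(exact * (1 - exact) / n_perm)
    assert abs(row["p"] - exact) <= max(3 * se, 1e-9)


def test_permutation_determinism():
    rng = np.random.default_rng(5)
    y = rng.random((40, 4))
    t = make_table(y, clusters=[0] * 20 + [1] * 20, layer="lognorm")
    pairs = LRPairList.from_frame(
        _pairs([("p1", "g0", "g1"), ("p2", "g2", "g3")]), t.gene_meta.index
    )
    params = InteractionParams(n_perm=300, seed=11)
    a = permutation_pvalues(t, pairs, params)
    b = permutation_pvalues(t, pairs, params)
    pd.testing.assert_frame_equal(a, b)


# --------------------------------------------------------------------------- #
# DEG pre-filter


def test_deg_prefilter_spike_in_and_flat_out():
    rng = np.random.default_rng(2)
    x = rng.poisson(4.0, size=(200, 10))
    clusters = [0] * 100 + [1] * 100
    x[:100, 0] = rng.poisson(16.0, size=100)  # 4-fold up in cluster 0, ~all express
    ln = normalize_log(make_table(x, clusters=clusters))
    genes = deg_prefilter(ln, [0], lfc=0.5, min_pct=0.25)
    assert "g0" in genes
    assert "g1" not in genes  # identical everywhere


def test_restrict_records_to_deg_genes():
    rec = pd.DataFrame(
        {"source": [0, 0], "target": [1, 1], "pair_id": ["a", "b"]}
    )
    pairs = LRPairList(
        pairs=pd.DataFrame(
            {
                "pair_id": ["a", "b"],
                "ligand": [("g0",), ("g5",)],
                "receptor": [("g1",), ("g6",)],
            }
        )
    )
    out = restrict_to_deg(rec, pairs, {"g0"})
    assert list(out["pair_id"]) == ["a"]


def test_missing_cluster_is_error():
    ln = make_table(np.ones((4, 2)), clusters=[0, 0, 1, 1], layer="lognorm")
    with pytest.raises(ValueError):
        deg_prefilter(ln, [7])
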