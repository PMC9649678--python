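"""Chain pairing, clonotype building, STARTRAC indices (with brute-force
oracles), matched T cells, and differential expression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lnmet import (
    build_clonotypes,
    classify_pairing,
    clonal_size_fractions,
    differential_expression,
    find_matched_t,
    normalize_log,
    startrac_expansion,
    startrac_transition,
    summarize_pairing,
)

from conftest import make_table


# --------------------------------------------------------------------------- #
# pairing


def _oracle_pairing(n_alpha, n_beta):
    """Independent restatement of the 7-category mapping."""
    if n_alpha == 0 and n_beta == 0:
        return None
    if max(n_alpha, n_beta) > 2:
        return "multichain"
    if (n_alpha, n_beta) == (1, 1):
        return "single_pair"
    if (n_alpha, n_beta) == (2, 2):
        return "two_full_chains"
    if n_beta == 0:
        return "orphan_alpha" if n_alpha == 1 else "extra_alpha"
    if n_alpha == 0:
        return "orphan_beta" if n_beta == 1 else "extra_beta"
    return "extra_alpha" if n_alpha == 2 else "extra_beta"


@pytest.mark.parametrize("na,nb", list(itertools.product(range(4), repeat=2)))
def test_pairing_mapping_exhaustive(na, nb):
    assert classify_pairing(na, nb) == _oracle_pairing(na, nb)


def test_summarize_pairing_ignores_nonproductive():
    contigs = pd.DataFrame(
        {
            "barcode": ["x-1", "x-1", "x-1"],
            "chain": ["TRA", "TRB", "TRA"],
            "cdr3": ["CAF", "CBF", "CCF"],
            "cdr3_nt": ["AAA", "CCC", "GGG"],
            "productive": [True, True, False],
        }
    )
    out = summarize_pairing(contigs)
    assert out.loc[0, "category"] == "single_pair"


# --------------------------------------------------------------------------- #
# clonotypes


def _contigs(rows):
    return pd.DataFrame(
        rows, columns=["barcode", "chain", "cdr3", "cdr3_nt", "productive"]
    )


def _meta(cells):
    return pd.DataFrame(
        cells, columns=["cell_id", "patient", "tissue", "cluster"]
    ).set_index("cell_id")


def test_same_chains_same_patient_one_clonotype():
    contigs = _contigs(
        [
            ("a-1", "TRA", "C1", "AAA", True),
            ("a-1", "TRB", "C2", "CCC", True),
            ("b-1", "TRA", "C1", "AAA", True),
            ("b-1", "TRB", "C2", "CCC", True),
        ]
    )
    meta = _meta([("a", "P1", "PT", 1), ("b", "P1", "LNMT", 1)])
    cl = build_clonotypes(contigs, meta)
    assert cl["clonotype_id"].nunique() == 1


def test_same_chains_different_patients_two_clonotypes():
    contigs = _contigs(
        [
            ("a-1", "TRA", "C1", "AAA", True),
            ("a-1", "TRB", "C2", "CCC", True),
            ("b-1", "TRA", "C1", "AAA", True),
            ("b-1", "TRB", "C2", "CCC", True),
        ]
    )
    meta = _meta([("a", "P1", "PT", 1), ("b", "P2", "PT", 1)])
    cl = build_clonotypes(contigs, meta)
    assert cl["clonotype_id"].nunique() == 2


def test_synthetic_repertoire_partition_matches_truth(default_dataset):
    ds = default_dataset
    cl = build_clonotypes(ds.tcr, ds.cells.cell_meta)
    truth = ds.truth.clonotype_truth.dropna()
    rec = cl.set_index("cell_id")["clonotype_id"]
    assert set(rec.index) == set(truth.index)
    # same partition: co-membership must agree
    a = pd.factorize(truth.loc[rec.index])[0]
    b = pd.factorize(rec)[0]
    assert ((a[:, None] == a[None, :]) == (b[:, None] == b[None, :])).all()


# --------------------------------------------------------------------------- #
# clonal size fractions


def test_clonal_fractions_all_singletons():
    cl = pd.DataFrame(
        {
            "cell_id": list("abc"),
            "patient": "P1",
            "tissue": "PT",
            "clonotype_id": ["x", "y", "z"],
        }
    )
    out = clonal_size_fractions(cl)
    assert tuple(out.iloc[0][["frac_size1", "frac_size2", "frac_size3plus"]]) == (1, 0, 0)


def test_clonal_fractions_worked_example():
    sizes = {"a": 3, "b": 2, "c": 1, "d": 1, "e": 1}
    rows = [
        {"cell_id": f"{k}{i}", "patient": "P1", "tissue": "PT", "clonotype_id": k}
        for k, n in sizes.items()
        for i in range(n)
    ]
    out = clonal_size_fractions(pd.DataFrame(rows))
    assert out.iloc[0]["frac_size1"] == pytest.approx(0.375)
    assert out.iloc[0]["frac_size2"] == pytest.approx(0.25)
    assert out.iloc[0]["frac_size3plus"] == pytest.approx(0.375)
    assert float(
        out[["frac_size1", "frac_size2", "frac_size3plus"]].iloc[0].sum()
    ) == pytest.approx(1.0)


# --------------------------------------------------------------------------- #
# STARTRAC oracles


def brute_expansion(clono_ids):
    """1 - normalized Shannon entropy, computed longhand."""
    if len(clono_ids) < 2:
        return float("nan")
    counts = {}
    for c in clono_ids:
        counts[c] = counts.get(c, 0) + 1
    if len(counts) == 1:
        return 1.0
    n = len(clono_ids)
    h = -sum((k / n) * math.log(k / n) for k in counts.values())
    return 1.0 - h / math.log(len(counts))


def brute_transition(cells):
    """cells: list of (clonotype, cluster). Returns {cluster: index}."""
    clusters = sorted({cl for _, cl in cells})
    K = len(clusters)
    if K < 2:
        return {}
    by_ct = {}
    for ct, cl in cells:
        by_ct.setdefault(ct, []).append(cl)
    trans = {}
    for ct, cls in by_ct.items():
        dist = {c: cls.count(c) / len(cls) for c in set(cls)}
        if len(dist) < 2:
            trans[ct] = 0.0
        else:
            h = -sum(p * math.log(p) for p in dist.values())
            trans[ct] = h / math.log(K)
    out = {}
    for c in clusters:
        cts = [ct for ct, cls in by_ct.items() if c in cls]
        w = [by_ct[ct].count(c) for ct in cts]  # clone size within cluster c
        out[c] = sum(wi * trans[ct] for wi, ct in zip(w, cts)) / sum(w)
    return out


def test_expansion_extremes():
    distinct = pd.DataFrame(
        {"cell_id": list("abcd"), "patient": "P", "tissue": "PT", "cluster": 1,
         "clonotype_id": list("wxyz")}
    )
    assert startrac_expansion(distinct)["expansion"].iloc[0] == pytest.approx(0.0)
    mono = distinct.assign(clonotype_id="w")
    assert startrac_expansion(mono)["expansion"].iloc[0] == 1.0


def test_expansion_hand_example_sizes_2_1_1():
    cl = pd.DataFrame(
        {"cell_id": list("abcd"), "patient": "P", "tissue": "PT", "cluster": 1,
         "clonotype_id": ["x", "x", "y", "z"]}
    )
    out = startrac_expansion(cl)["expansion"].iloc[0]
    assert out == pytest.approx(1 - 1.0397207708399179 / math.log(3), abs=1e-6)
    assert out == pytest.approx(0.0536, abs=2e-4)


def test_transition_hand_example():
    # clonotype c1: 2 cells in A, 2 in B; c2: 2 cells only in A
    rows = (
        [("c1", "A")] * 2 + [("c1", "B")] * 2 + [("c2", "A")] * 2
    )
    cl = pd.DataFrame(
        {
            "cell_id": [f"x{i}" for i in range(6)],
            "patient": "P",
            "tissue": "PT",
            "cluster": [c for _, c in rows],
            "clonotype_id": [ct for ct, _ in rows],
        }
    )
    out = startrac_transition(cl).set_index("cluster")["transition"]
    assert out["A"] == pytest.approx(0.5)
    assert out["B"] == pytest.approx(1.0)


def test_indices_match_brute_force_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(2, 51)
        k = rng.integers(2, 6)
        cl = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "patient": "P",
                "tissue": "PT",
                "cluster": rng.integers(0, k, n),
                "clonotype_id": [f"ct{j}" for j in rng.integers(0, max(2, n // 2), n)],
            }
        )
        exp = startrac_expansion(cl, grouping=("patient", "tissue"))
        assert exp["expansion"].iloc[0] == pytest.approx(
            brute_expansion(list(cl["clonotype_id"])), abs=1e-12
        )
        got = startrac_transition(cl).set_index("cluster")["transition"]
        want = brute_transition(list(zip(cl["clonotype_id"], cl["cluster"])))
        for c, v in want.items():
            assert got[c] == pytest.approx(v, abs=1e-12)
            assert 0.0 <= got[c] <= 1.0 + 1e-12


def test_indices_invariant_to_cell_order():
    rng = np.random.default_rng(3)
    cl = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(30)],
            "patient": "P",
            "tissue": "PT",
            "cluster": rng.integers(0, 3, 30),
            "clonotype_id": [f"ct{j}" for j in rng.integers(0, 8, 30)],
        }
    )
    shuffled = cl.sample(frac=1.0, random_state=1)
    pd.testing.assert_frame_equal(
        startrac_transition(cl), startrac_transition(shuffled)
    )


# --------------------------------------------------------------------------- #
# matched T


def test_single_tissue_clonotype_not_matched():
    cl = pd.DataFrame(
        {
            "cell_id": ["a", "b", "c", "d"],
            "patient": "P1",
            "tissue": ["PT", "PT", "PT", "LNMT"],
            "clonotype_id": ["x", "x", "x", "y"],
        }
    )
    mt = find_matched_t(cl)
    assert not mt.matched.any()


def test_cross_tissue_clonotype_all_members_matched():
    cl = pd.DataFrame(
        {
            "cell_id": ["a", "b", "c", "d"],
            "patient": "P1",
            "tissue": ["PT", "PT", "PT", "LNMT"],
            "clonotype_id": ["x", "x", "x", "x"],
        }
    )
    mt = find_matched_t(cl)
    assert mt.matched.all()


def test_single_tissue_patient_excluded():
    cl = pd.DataFrame(
        {
            "cell_id": ["a", "b"],
            "patient": ["P1", "P1"],
            "tissue": ["PT", "PT"],
            "clonotype_id": ["x", "x"],
        }
    )
    mt = find_matched_t(cl)
    assert mt.excluded_patients == ["P1"]
    assert len(mt.matched) == 0


# --------------------------------------------------------------------------- #
# differential expression


def test_de_planted_spike_detected_with_correct_lfc():
    rng = np.random.default_rng(0)
    n = 100
    base = rng.poisson(5.0, size=(2 * n, 30))
    base[:n, 0] = rng.poisson(20.0, size=n)  # 4-fold spike in group A
    t = make_table(base)
    ln = normalize_log(t, scale=1e4)
    de = differential_expression(
        ln, ln.cell_meta.index[:n], ln.cell_meta.index[n:], lfc_cut=0.25
    )
    assert bool(de.loc[0, "significant"])
    assert de.loc[0, "direction"] == "up"
    assert 1.3 < de.loc[0, "log2fc"] < 2.7


def test_de_null_has_no_significant_genes():
    rng = np.random.default_rng(1)
    x = rng.poisson(3.0, size=(120, 40))
    ln = normalize_log(make_table(x))
    de = differential_expression(ln, ln.cell_meta.index[:60], ln.cell_meta.index[60:])
    assert de["significant"].sum() <= 1


def test_de_small_group_rejected():
    ln = normalize_log(make_table(np.ones((6, 4), dtype=int)))
    with pytest.raises(ValueError):
        differential_expression(ln, ln.cell_meta.index[:2], ln.cell_meta.index[2:])
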