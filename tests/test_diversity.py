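"""Faith PD, weighted UniFrac, phenotype beta diversity, distance summaries."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as skbio_faith_pd
from skbio.diversity.beta import weighted_unifrac as skbio_weighted_unifrac

from scfaprof import (
    carrier_subcommunities,
    cpi_vs_ad_bins,
    faith_pd,
    group_distance_summary,
    pbd_rpbd,
    weighted_unifrac,
)
from scfaprof.rules import PRODUCTS


def _tree(newick):
    return TreeNode.read(_io.StringIO(newick))


THREE_LEAF = "((a:1.0,b:2.0):1.5,c:3.0)root;"


def _random_tree(rng, n_leaves):
    items = [f"l{i}:{rng.uniform(0.1, 2.0):.3f}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = rng.choice(len(items), size=2, replace=False)
        a, b = items[i], items[j]
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        if len(items) == 0:
            items.append(f"({a},{b})root;")
        else:
            items.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.3f}")
    return _tree(items[0])


def _enumerate_unifrac(pa, pb, tree):
    """Independent oracle: per-branch sums with descendant sets collected by
    walking each leaf's ancestor path."""
    total_a, total_b = sum(pa.values()), sum(pb.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in tree.tips() if node in t.ancestors() or node is t}
        fa = sum(pa.get(t, 0.0) for t in tips) / total_a
        fb = sum(pb.get(t, 0.0) for t in tips) / total_b
        b = node.length or 0.0
        num += b * abs(fa - fb)
        den += b * (fa + fb)
    return num / den if den else 0.0


# --- Faith PD -----------------------------------------------------------------

def test_faith_pd_all_leaves_is_total_branch_length():
    tree = _tree(THREE_LEAF)
    assert faith_pd(["a", "b", "c"], tree) == pytest.approx(7.5)


def test_faith_pd_single_leaf_is_root_path():
    tree = _tree(THREE_LEAF)
    assert faith_pd(["a"], tree) == pytest.approx(2.5)
    assert faith_pd(["c"], tree) == pytest.approx(3.0)


def test_faith_pd_two_of_three_leaves():
    tree = _tree(THREE_LEAF)
    # spanning subtree of {a, c}: branches a (1.0), inner (1.5), c (3.0)
    assert faith_pd(["a", "c"], tree) == pytest.approx(5.5)


def test_faith_pd_monotone_and_matches_skbio():
    rng = np.random.default_rng(21)
    for _ in range(5):
        n = int(rng.integers(3, 8))
        tree = _random_tree(rng, n)
        leaves = [t.name for t in tree.tips()]
        subset = list(rng.choice(leaves, size=max(1, n // 2), replace=False))
        pd_sub = faith_pd(subset, tree)
        pd_more = faith_pd(subset + [l for l in leaves if l not in subset][:1], tree)
        assert pd_more >= pd_sub - 1e-12
        counts = [1 if l in subset else 0 for l in leaves]
        assert pd_sub == pytest.approx(
            float(skbio_faith_pd(counts, taxa=leaves, tree=tree)), abs=1e-9
        )


def test_faith_pd_unknown_leaf_is_error():
    with pytest.raises(ValueError, match="absent"):
        faith_pd(["zz"], _tree(THREE_LEAF))


# --- weighted UniFrac ----------------------------------------------------------

def test_unifrac_identity_and_symmetry():
    tree = _tree(THREE_LEAF)
    s = {"a": 0.2, "b": 0.3, "c": 0.5}
    t = {"a": 0.6, "c": 0.4}
    assert weighted_unifrac(s, s, tree) == pytest.approx(0.0)
    assert weighted_unifrac(s, t, tree) == pytest.approx(weighted_unifrac(t, s, tree))


def test_unifrac_disjoint_star_tree_is_one():
    tree = _tree("(a:1.0,b:1.0,c:1.0)root;")
    assert weighted_unifrac({"a": 1.0}, {"b": 1.0}, tree) == pytest.approx(1.0)


def test_unifrac_empty_sample_is_error():
    with pytest.raises(ValueError, match="empty"):
        weighted_unifrac({}, {"a": 1.0}, _tree(THREE_LEAF))


def test_unifrac_three_leaf_matches_enumeration():
    tree = _tree(THREE_LEAF)
    pa = {"a": 0.5, "b": 0.25, "c": 0.25}
    pb = {"a": 0.1, "c": 0.9}
    assert weighted_unifrac(pa, pb, tree) == pytest.approx(
        _enumerate_unifrac(pa, pb, tree), abs=1e-12
    )


def test_unifrac_random_small_trees_match_oracles():
    """All seeded trees with <= 5 leaves: agreement with the exhaustive
    branch enumeration and with scikit-bio's implementation."""
    rng = np.random.default_rng(33)
    for n in (2, 3, 4, 5):
        for _ in range(6):
            tree = _random_tree(rng, n)
            leaves = [t.name for t in tree.tips()]
            wa = rng.dirichlet(np.ones(n))
            wb = rng.dirichlet(np.ones(n))
            pa = dict(zip(leaves, wa))
            pb = dict(zip(leaves, wb))
            d = weighted_unifrac(pa, pb, tree)
            assert 0.0 <= d <= 1.0 + 1e-12
            assert d == pytest.approx(_enumerate_unifrac(pa, pb, tree), abs=1e-10)
            # skbio expects integer count vectors
            ca = np.round(wa * 10**7).astype(int)
            cb = np.round(wb * 10**7).astype(int)
            d_skbio = float(
                skbio_weighted_unifrac(ca, cb, taxa=leaves, tree=tree, normalized=True)
            )
            assert d == pytest.approx(d_skbio, abs=1e-5)


# --- carrier sub-communities and PBD -------------------------------------------

def _pis(values):
    return pd.DataFrame(
        {p: values for p in PRODUCTS}, index=list(values.keys())
    )


def test_carrier_threshold_inclusive():
    table = pd.DataFrame({"a": [0.5], "b": [0.5]}, index=["s1"])
    pis = _pis({"a": 0.5, "b": 0.4})
    subs = carrier_subcommunities(table, pis, "butyrate")
    assert subs["s1"].carriers == ("a",)
    assert subs["s1"].abundances.loc["a"] == pytest.approx(1.0)
    none = carrier_subcommunities(table, _pis({"a": 0.1, "b": 0.2}), "butyrate")
    assert none["s1"].empty


def test_pbd_equals_bd_when_all_carriers():
    tree = _tree(THREE_LEAF)
    table = pd.DataFrame(
        {"a": [0.2, 0.5], "b": [0.3, 0.1], "c": [0.5, 0.4]}, index=["s1", "s2"]
    )
    pis = _pis({"a": 1.0, "b": 1.0, "c": 1.0})
    pbd, rpbd, bd = pbd_rpbd(table, pis, "butyrate", tree)
    assert np.allclose(pbd.to_numpy(), bd.to_numpy(), atol=1e-12)
    off = ~np.eye(2, dtype=bool)
    assert np.allclose(rpbd.to_numpy()[off], 1.0)


def test_pbd_matches_manual_restriction():
    tree = _tree(THREE_LEAF)
    table = pd.DataFrame(
        {"a": [0.2, 0.6], "b": [0.3, 0.1], "c": [0.5, 0.3]}, index=["s1", "s2"]
    )
    pis = _pis({"a": 1.0, "b": 0.0, "c": 1.0})
    pbd, rpbd, bd = pbd_rpbd(table, pis, "butyrate", tree)
    manual = weighted_unifrac(
        {"a": 0.2 / 0.7, "c": 0.5 / 0.7}, {"a": 0.6 / 0.9, "c": 0.3 / 0.9}, tree
    )
    assert pbd.loc["s1", "s2"] == pytest.approx(manual, abs=1e-12)
    assert rpbd.loc["s1", "s2"] == pytest.approx(manual / bd.loc["s1", "s2"])


def test_identical_carrier_subcommunities_have_zero_pbd():
    tree = _tree(THREE_LEAF)
    table = pd.DataFrame(
        {"a": [0.2, 0.4], "b": [0.1, 0.2], "c": [0.7, 0.4]}, index=["s1", "s2"]
    )
    # carriers a and b keep the 2:1 ratio in both samples
    pis = _pis({"a": 1.0, "b": 1.0, "c": 0.0})
    pbd, _, _ = pbd_rpbd(table, pis, "butyrate", tree)
    assert pbd.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-12)


# --- distance summaries and binning ---------------------------------------------

def test_group_distance_summary_block_matrix():
    samples = ["a1", "a2", "b1", "b2"]
    d = pd.DataFrame(1.0, index=samples, columns=samples)
    for g in (("a1", "a2"), ("b1", "b2")):
        d.loc[g[0], g[1]] = d.loc[g[1], g[0]] = 0.0
    np.fill_diagonal(d.to_numpy(), 0.0)
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    out = group_distance_summary(d, groups).set_index(["group_a", "group_b"])
    assert out.loc[("A", "A"), "mean_distance"] == pytest.approx(0.0)
    assert out.loc[("B", "B"), "mean_distance"] == pytest.approx(0.0)
    assert out.loc[("A", "B"), "mean_distance"] == pytest.approx(1.0)


def test_group_distance_summary_matches_enumeration():
    rng = np.random.default_rng(55)
    samples = [f"s{i}" for i in range(6)]
    m = rng.random((6, 6))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    d = pd.DataFrame(m, index=samples, columns=samples)
    groups = pd.Series(["X", "X", "X", "Y", "Y", "Y"], index=samples)
    out = group_distance_summary(d, groups).set_index(["group_a", "group_b"])
    intra_x = np.mean([m[0, 1], m[0, 2], m[1, 2]])
    inter = np.mean([m[i, j] for i in range(3) for j in range(3, 6)])
    assert out.loc[("X", "X"), "mean_distance"] == pytest.approx(intra_x)
    assert out.loc[("X", "Y"), "mean_distance"] == pytest.approx(inter)


def test_cpi_vs_ad_bins():
    idx = [f"s{i}" for i in range(20)]
    ad = pd.Series(np.linspace(0, 10, 20), index=idx)
    cpi_const = pd.Series(0.4, index=idx)
    out = cpi_vs_ad_bins(cpi_const, ad, 4)
    assert np.allclose(out["cpi_median"].dropna(), 0.4)
    cpi_lin = pd.Series(np.linspace(0, 1, 20), index=idx)
    out = cpi_vs_ad_bins(cpi_lin, ad, 4)
    medians = out["cpi_median"].to_numpy()
    assert (np.diff(medians) > 0).all()
    single = cpi_vs_ad_bins(cpi_lin.iloc[:1], ad.iloc[:1], 3)
    assert single["count"].sum() == 1
    with pytest.raises(ValueError):
        cpi_vs_ad_bins(cpi_lin, ad, 0)
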