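"""Bimodal LRT, BH correction and the two-stage marker logic."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from scfibro import (MarkerCaller, bh_fdr, bimod_lrt, deg_one_vs_rest,
                     deg_pairwise, overlap_markers, posthoc_cluster_validity,
                     top_markers)
from scfibro.cluster import ClusterAssignment


def _assignment(labels):
    labels = list(labels)
    table = pd.DataFrame({"pass1": labels, "final": labels,
                          "reason": ["none"] * len(labels)},
                         index=[f"c{i}" for i in range(len(labels))])
    return ClusterAssignment(table)


def _planted_expr(rng, n_per=60, n_genes=30, shift=2.0, n_clusters=3,
                  markers_each=4):
    """Zero-inflated background with ``markers_each`` up-shifted genes per
    cluster; returns (expr, assignment, {cluster: marker genes})."""
    n = n_per * n_clusters
    base = np.where(rng.random((n, n_genes)) < 0.4, 0.0,
                    np.abs(rng.normal(1.0, 0.3, (n, n_genes))))
    planted = {}
    for c in range(n_clusters):
        genes = list(range(c * markers_each, (c + 1) * markers_each))
        base[c * n_per:(c + 1) * n_per, genes] += shift
        planted[c] = {f"g{g}" for g in genes}
    expr = pd.DataFrame(base, index=[f"c{i}" for i in range(n)],
                        columns=[f"g{i}" for i in range(n_genes)])
    labels = np.repeat(range(n_clusters), n_per)
    return expr, _assignment(labels), planted


# --- bimod_lrt ---------------------------------------------------------------

def test_bimod_identical_groups():
    vals = np.array([0.0, 1.2, 0.0, 2.5, 3.1, 0.0, 1.8, 2.2])
    stat, p = bimod_lrt(vals, vals)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_bimod_all_zero_groups():
    stat, p = bimod_lrt(np.zeros(10), np.zeros(15))
    assert (stat, p) == (0.0, 1.0)


def test_bimod_empty_group_raises():
    with pytest.raises(ValueError, match="non-empty"):
        bimod_lrt([], [1.0])


def test_bimod_detects_mean_shift(rng):
    a = np.abs(rng.normal(1.0, 0.3, 100))
    stat, p = bimod_lrt(a, a + 2.0)
    assert p < 1e-10
    assert stat > 0


def test_bimod_detects_detection_rate_shift(rng):
    """Same positive mean, different zero fraction, is still detected."""
    pos = np.abs(rng.normal(2.0, 0.2, 200))
    a = np.where(rng.random(200) < 0.8, 0.0, pos)
    b = np.where(rng.random(200) < 0.2, 0.0, pos)
    _, p = bimod_lrt(a, b)
    assert p < 1e-6


def test_bimod_null_pvalues_uniform(rng):
    """Under the null (both groups drawn from one zero-inflated normal) the
    p-values are uniform: Kolmogorov-Smirnov at alpha 0.01, 1000 genes."""
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(1000):
        pool = np.where(rng.random(200) < 0.4, 0.0,
                        np.abs(rng.normal(2.0, 0.7, 200)))
        ps.append(bimod_lrt(pool[:100], pool[100:])[1])
    assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


# --- bh_fdr ------------------------------------------------------------------

def test_bh_fdr_toy_oracle():
    """Step-up on (0.01, 0.02, 0.03, 0.04): q_i = p_i * 4 / i, then a
    cumulative min from the largest, giving 0.04 everywhere."""
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, 0.04)


def test_bh_fdr_hand_computed():
    q = bh_fdr([0.005, 0.5, 0.04])
    # ranks: 0.005 -> 1, 0.04 -> 2, 0.5 -> 3
    assert np.allclose(q, [0.015, 0.5, 0.06])


def test_bh_fdr_preserves_order_and_bounds(rng):
    p = rng.random(200)
    q = bh_fdr(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0).all()
    # monotone in p
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_fdr_empty_and_invalid():
    assert bh_fdr([]).size == 0
    with pytest.raises(ValueError, match="p-values"):
        bh_fdr([0.5, 1.5])


# --- stage 1 / stage 2 -------------------------------------------------------

def test_stage1_recovers_planted_markers(rng):
    expr, asg, planted = _planted_expr(rng)
    set1 = deg_one_vs_rest(expr, asg)
    for c, genes in planted.items():
        found = set(set1.loc[set1["cluster"] == c, "gene"])
        assert genes <= found


def test_stage1_threshold_monotone(rng):
    """Raising either threshold can only shrink the DEG set; a threshold at
    the realized maximum effect excludes everything (strict comparison)."""
    expr, asg, _ = _planted_expr(rng)
    loose = deg_one_vs_rest(expr, asg, min_log_diff=0.25)
    tight = deg_one_vs_rest(expr, asg, min_log_diff=1.0)
    keys = lambda t: set(zip(t["gene"], t["cluster"]))
    assert keys(tight) <= keys(loose)
    top = loose["avg_log_diff"].max()
    assert deg_one_vs_rest(expr, asg, min_log_diff=float(top)).empty


def test_stage2_requires_every_cluster(rng):
    """A gene raised in clusters 0 AND 1 (vs 2) separates neither 0 from 1,
    so it enters no stage-2 set; a gene unique to cluster 0 enters set 0."""
    n_per = 60
    base = np.where(rng.random((3 * n_per, 2)) < 0.4, 0.0,
                    np.abs(rng.normal(1.0, 0.3, (3 * n_per, 2))))
    base[:2 * n_per, 0] += 2.0       # shared between clusters 0 and 1
    base[:n_per, 1] += 2.0           # unique to cluster 0
    expr = pd.DataFrame(base, columns=["shared", "unique"],
                        index=[f"c{i}" for i in range(3 * n_per)])
    asg = _assignment(np.repeat([0, 1, 2], n_per))
    set2 = deg_pairwise(expr, asg)
    assert "shared" not in set2[0] and "shared" not in set2[1]
    assert "unique" in set2[0]
    assert set2[1] == set() and set2[2] == set()


def test_stage_warns_single_cluster(rng):
    expr = pd.DataFrame(rng.random((20, 3)),
                        index=[f"c{i}" for i in range(20)])
    asg = _assignment([0] * 20)
    with pytest.warns(UserWarning, match="fewer than 2"):
        assert deg_one_vs_rest(expr, asg).empty
    with pytest.warns(UserWarning, match="fewer than 2"):
        assert deg_pairwise(expr, asg) == {0: set()}


# --- overlap / validity / top ------------------------------------------------

def test_overlap_is_intersection():
    set1 = pd.DataFrame({
        "gene": ["a", "b", "c"], "cluster": [0, 0, 1],
        "avg_log_diff": [2.0, 1.0, 1.5], "p": [1e-8] * 3, "q": [1e-6] * 3,
        "direction": [1] * 3,
    })
    set2 = {0: {"b", "d"}, 1: {"c"}}
    table = overlap_markers(set1, set2)
    markers = set(zip(table.loc[table["is_marker"], "gene"],
                      table.loc[table["is_marker"], "cluster"]))
    assert markers == {("b", 0), ("c", 1)}
    # union is present with membership flags
    d_row = table[(table["gene"] == "d") & (table["cluster"] == 0)].iloc[0]
    assert not d_row["in_set1"] and d_row["in_set2"] and not d_row["is_marker"]
    assert np.isnan(d_row["avg_log_diff"])


def test_overlap_set2_subset_of_set1():
    """When every stage-2 gene also passed stage 1, markers == stage-2 set."""
    set1 = pd.DataFrame({
        "gene": ["a", "b"], "cluster": [0, 0],
        "avg_log_diff": [2.0, 1.0], "p": [1e-8] * 2, "q": [1e-6] * 2,
        "direction": [1] * 2,
    })
    table = overlap_markers(set1, {0: {"a"}})
    assert set(table.loc[table["is_marker"], "gene"]) == {"a"}


def test_posthoc_validity_counts(rng):
    expr, asg, planted = _planted_expr(rng, shift=2.5, markers_each=6)
    validity = posthoc_cluster_validity(expr, asg, min_log_diff=1.0,
                                        max_fdr=0.01, min_degs=10)
    assert len(validity) == 3  # unordered pairs of 3 clusters
    # each pair differs in the two clusters' planted blocks: 12 genes > 10
    assert (validity["n_degs"] >= 12).all()
    assert validity["pass"].all()


def test_posthoc_min_degs_strict(rng):
    expr, asg, _ = _planted_expr(rng, n_clusters=2, markers_each=3,
                                 shift=2.5)
    validity = posthoc_cluster_validity(expr, asg, min_degs=6)
    # exactly 6 planted DEGs for the single pair; > 6 is false
    assert validity.loc[0, "n_degs"] == 6
    assert not validity.loc[0, "pass"]


def test_top_markers_n_and_tiebreak():
    table = pd.DataFrame({
        "gene": ["g3", "g1", "g2", "g4"],
        "cluster": [0, 0, 0, 1],
        "avg_log_diff": [1.0, 1.0, 2.0, 1.0],
        "p": [1e-9] * 4,
        "q": [1e-3, 1e-6, 1e-6, 1e-6],
        "direction": [1] * 4,
        "is_marker": [True] * 4,
    })
    picked, heat = top_markers(table, n=2)
    c0 = picked[picked["cluster"] == 0]["gene"].tolist()
    # g2 first (largest effect); tie between g1/g3 broken by smaller q
    assert c0 == ["g2", "g1"]
    assert heat is None


def test_top_markers_heatmap(rng):
    expr, asg, _ = _planted_expr(rng)
    caller = MarkerCaller().fit(expr, asg)
    picked, heat = top_markers(caller.markers_, n=3, expr=expr, assign=asg)
    assert heat is not None
    assert list(heat.columns) == [0, 1, 2]
    assert set(picked["gene"]) <= set(heat.index)


def test_top_markers_empty_raises():
    with pytest.raises(ValueError, match="empty"):
        top_markers(pd.DataFrame(columns=["gene", "cluster"]))


def test_marker_caller_end_to_end(rng):
    # 6 markers per cluster so every pair differs in 12 genes, clearing the
    # strict > 10 post-hoc validity bar
    expr, asg, planted = _planted_expr(rng, markers_each=6)
    caller = MarkerCaller().fit(expr, asg)
    called = caller.markers_[caller.markers_["is_marker"]]
    for c, genes in planted.items():
        assert genes <= set(called.loc[called["cluster"] == c, "gene"])
    assert caller.validity_["pass"].all()
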