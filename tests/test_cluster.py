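"""Two-pass DBSCAN, removal accounting, composition tests, subclustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import DBSCAN
from sklearn.metrics import adjusted_rand_score

from scfibro import (TwoPassDBSCAN, composition_by_group, dbscan_two_pass,
                     removed_percent, subcluster)


def _blobs(rng, centers, sizes, sd=0.15):
    """Tight 2-D Gaussian blobs as a coordinate DataFrame."""
    pts, names = [], []
    for i, (c, n) in enumerate(zip(centers, sizes)):
        pts.append(rng.normal(c, sd, size=(n, 2)))
        names += [f"b{i}_{j}" for j in range(n)]
    return pd.DataFrame(np.vstack(pts), index=names,
                        columns=["tsne1", "tsne2"])


# --- removed_percent ---------------------------------------------------------

def test_removed_percent_truncates():
    """320 of 27,744 is 1.1534...%, reported as 1.1 (floor, not round)."""
    assert removed_percent(320, 27744) == 1.1
    assert removed_percent(199, 1000) == 19.9
    assert removed_percent(1, 3, decimals=2) == 33.33
    assert removed_percent(0, 5) == 0.0


def test_removed_percent_invalid_total():
    with pytest.raises(ValueError, match="n_total"):
        removed_percent(1, 0)


# --- brute-force DBSCAN oracle -----------------------------------------------

def _dbscan_oracle(coords, eps, min_pts):
    """Straightforward O(n^2) DBSCAN: core points, BFS over core
    neighborhoods, then border attachment."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    neigh = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neigh])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack, labels[i] = [i], cid
        while stack:
            j = stack.pop()
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dbscan_matches_brute_force_oracle(seed):
    """sklearn DBSCAN (as used inside TwoPassDBSCAN) partitions points
    identically to an O(n^2) textbook implementation, up to label names and
    ambiguous border points (border cells reachable from several clusters);
    core and noise points must agree exactly."""
    rng = np.random.default_rng(seed)
    coords = _blobs(rng, [(0, 0), (3, 0), (0, 3)], [150, 150, 100],
                    sd=0.4).to_numpy()
    eps, min_pts = 0.5, 10
    ours = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    oracle = _dbscan_oracle(coords, eps, min_pts)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    n_neigh = (d <= eps).sum(axis=1)
    core = n_neigh >= min_pts
    # noise agreement is exact for core points; border points may be noise
    # in one and assigned in the other only if non-core
    disagree_noise = (ours == -1) != (oracle == -1)
    assert not (disagree_noise & core).any()
    # partition of core points identical up to relabeling
    assert adjusted_rand_score(ours[core], oracle[core]) == 1.0


# --- TwoPassDBSCAN -----------------------------------------------------------

def test_two_pass_prunes_small_blob_and_noise(rng):
    """Blobs of 100/50/5 points plus scattered noise: the 5-point blob and
    the noise are removed; two clusters remain, largest first."""
    coords = _blobs(rng, [(0, 0), (5, 5), (10, 0)], [100, 50, 5])
    noise = pd.DataFrame(rng.uniform(-20, 20, size=(15, 2)),
                         index=[f"n{i}" for i in range(15)],
                         columns=["tsne1", "tsne2"])
    # keep scattered points isolated so they are DBSCAN noise
    noise = noise[(np.abs(noise["tsne1"]) > 12) | (noise["tsne2"] < -3)]
    coords = pd.concat([coords, noise])
    asg = dbscan_two_pass(coords, eps1=0.5, min_size1=10, eps2=1.0,
                          min_size2=20, min_pts=4)
    assert asg.n_clusters == 2
    assert list(asg.cluster_sizes) == [100, 50]  # descending by size
    # every blob-0 cell in final cluster 0, blob-1 in cluster 1
    assert (asg.final.loc[[f"b0_{j}" for j in range(100)]] == 0).all()
    assert (asg.final.loc[[f"b1_{j}" for j in range(50)]] == 1).all()
    assert (asg.final.loc[[f"b2_{j}" for j in range(5)]] == -1).all()


def test_reason_ledger_reconciles(rng):
    coords = _blobs(rng, [(0, 0), (6, 6), (12, 0)], [80, 30, 6])
    asg = dbscan_two_pass(coords, eps1=0.5, min_size1=10, eps2=1.0,
                          min_size2=20, min_pts=4)
    counts = asg.removal_counts()
    assert counts.get("none", 0) == len(asg.retained)
    removed_reasons = {"noise_pass1", "small_cluster_pass1", "noise_pass2",
                       "small_cluster_pass2"}
    assert sum(counts.get(r, 0) for r in removed_reasons) == asg.n_removed
    assert asg.removed_percent() == removed_percent(asg.n_removed,
                                                    len(asg.table))


def test_two_pass_label_order_ties(rng):
    """Final labels are 0..k-1 and sizes are non-increasing."""
    coords = _blobs(rng, [(0, 0), (6, 0), (0, 6), (6, 6)], [40, 60, 50, 60])
    asg = dbscan_two_pass(coords, eps1=0.5, min_size1=10, eps2=1.0,
                          min_size2=20, min_pts=4)
    sizes = asg.cluster_sizes
    assert list(sizes.index) == list(range(len(sizes)))
    assert all(np.diff(sizes.to_numpy()) <= 0)


def test_two_pass_all_noise_raises(rng):
    coords = pd.DataFrame(rng.uniform(-100, 100, size=(30, 2)),
                          columns=["tsne1", "tsne2"])
    with pytest.raises(ValueError, match="pass 1 removed every cell"):
        dbscan_two_pass(coords, eps1=0.01, min_pts=5)


def test_two_pass_too_few_points():
    coords = pd.DataFrame([[0.0, 0.0]], columns=["tsne1", "tsne2"])
    with pytest.raises(ValueError, match="min_pts"):
        TwoPassDBSCAN(min_pts=10).fit(coords)


def test_two_pass_accepts_embedding_object(rng):
    from scfibro import Embedding
    coords = _blobs(rng, [(0, 0), (5, 5)], [60, 40])
    emb = Embedding(coords=coords, params={})
    asg = dbscan_two_pass(emb, min_pts=4)
    assert asg.n_clusters == 2


# --- composition -------------------------------------------------------------

def _toy_assignment():
    labels = ["A"] * 40 + ["B"] * 40
    final = [0] * 10 + [1] * 30 + [0] * 30 + [1] * 10
    table = pd.DataFrame({"pass1": final, "final": final,
                          "reason": ["none"] * 80},
                         index=[f"c{i}" for i in range(80)])
    from scfibro.cluster import ClusterAssignment
    meta = pd.DataFrame({"condition": labels}, index=table.index)
    return ClusterAssignment(table), meta


def test_composition_proportions_and_tests():
    """Cluster 0 holds 10/40 of condition A and 30/40 of condition B."""
    asg, meta = _toy_assignment()
    comp = composition_by_group(asg, meta)
    assert comp.proportions.loc[0, "A"] == pytest.approx(0.25)
    assert comp.proportions.loc[0, "B"] == pytest.approx(0.75)
    assert np.allclose(comp.proportions.sum(axis=0), 1.0)
    # z-test agrees with a direct two-proportion computation
    row = comp.tests[(comp.tests["cluster"] == 0)].iloc[0]
    from statsmodels.stats.proportion import proportions_ztest
    _, p_ref = proportions_ztest([10, 30], [40, 40])
    assert row["p"] == pytest.approx(p_ref)
    assert row["q"] >= row["p"] - 1e-15
    assert set(comp.tests.columns) >= {"cluster", "condition_a",
                                       "condition_b", "count_a", "count_b",
                                       "p", "q"}


def test_composition_excludes_removed_cells():
    asg, meta = _toy_assignment()
    asg.table.loc["c0", "final"] = -1
    comp = composition_by_group(asg, meta)
    assert comp.counts.to_numpy().sum() == 79


def test_composition_empty_condition_raises():
    asg, meta = _toy_assignment()
    # condition C exists in metadata categories but has no retained cells
    meta["condition"] = pd.Categorical(meta["condition"],
                                       categories=["A", "B", "C"])
    with pytest.raises(ValueError, match="no retained cells"):
        composition_by_group(asg, meta)


def test_composition_degenerate_extremes():
    """All-zero and all-cells clusters get p = 1 (no information)."""
    from scfibro.cluster import ClusterAssignment
    final = [0] * 20
    table = pd.DataFrame({"pass1": final, "final": final,
                          "reason": ["none"] * 20},
                         index=[f"c{i}" for i in range(20)])
    meta = pd.DataFrame({"condition": ["A"] * 10 + ["B"] * 10},
                        index=table.index)
    comp = composition_by_group(ClusterAssignment(table), meta)
    assert (comp.tests["p"] == 1.0).all()


# --- subcluster --------------------------------------------------------------

def test_subcluster_splits_merged_blob(rng):
    """Cells whose expression separates two groups the parent clustering
    merged: subclustering recovers both, ARI 1 vs the planted split."""
    n = 120
    expr = pd.DataFrame(rng.normal(0, 0.05, size=(n, 30)),
                        index=[f"c{i}" for i in range(n)],
                        columns=[f"g{i}" for i in range(30)])
    expr.iloc[:60, :10] += 0.2   # group 1 program, means inside HVG window
    expr.iloc[60:, 10:20] += 0.2
    expr = expr.clip(lower=0)
    from scfibro.cluster import ClusterAssignment
    table = pd.DataFrame({"pass1": 0, "final": 0, "reason": "none"},
                         index=expr.index)
    parent = ClusterAssignment(table)
    child = subcluster(expr, parent, target_cluster=0, seed=0,
                       perplexity=20,
                       dbscan_kwargs=dict(min_pts=5, min_size1=5,
                                          min_size2=10))
    kept = child.retained
    truth = (pd.Series(range(n), index=expr.index) < 60).astype(int)
    assert child.n_clusters == 2
    assert adjusted_rand_score(truth.loc[kept], child.final.loc[kept]) == 1.0
    names = set(child.table["final_namespaced"])
    assert names <= {"0.0", "0.1", "removed"}
    assert child.table.attrs["parent_cluster"] == 0


def test_subcluster_missing_cluster():
    from scfibro.cluster import ClusterAssignment
    table = pd.DataFrame({"pass1": [0] * 20, "final": [0] * 20,
                          "reason": ["none"] * 20})
    expr = pd.DataFrame(np.zeros((20, 5)))
    with pytest.raises(ValueError, match="does not exist"):
        subcluster(expr, ClusterAssignment(table), target_cluster=3)
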