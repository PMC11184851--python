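"""Two-pass DBSCAN clustering on the tSNE map, with pruning and accounting.

Pass 1 runs DBSCAN at a small radius; noise cells and members of clusters
smaller than ``min_size1`` are removed. Pass 2 re-runs DBSCAN at a larger
radius on the surviving cells of the *same* embedding; pass-2 noise and
clusters smaller than ``min_size2`` are removed as well. Final labels are
contiguous integers ordered by descending cluster size, and every removed
cell carries the reason it was dropped.

Also provides per-condition composition statistics (two-proportion z-tests
with Benjamini-Hochberg correction) and subclustering, which re-runs the
HVG -> PCA -> tSNE -> DBSCAN chain on one cluster's cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "ClusterAssignment",
    "TwoPassDBSCAN",
    "dbscan_two_pass",
    "CompositionTable",
    "composition_by_group",
    "subcluster",
    "removed_percent",
]

NOISE = -1
REMOVED = -1


def removed_percent(n_removed: int, n_total: int, decimals: int = 1) -> float:
    """Removed-cell percentage, truncated (not rounded) to ``decimals``.

    Truncation matches the convention used when reporting pruning losses,
    e.g. 320 of 27,744 cells -> 1.1%.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    scale = 10 ** decimals
    return math.floor(100.0 * n_removed / n_total * scale) / scale


@dataclass
class ClusterAssignment:
    """Per-cell labels from the two-pass procedure.

    ``final`` is a contiguous 0-based cluster label or ``-1`` for removed
    cells; ``pass1`` keeps the raw first-pass DBSCAN label (``-1`` = noise);
    ``reason`` is one of ``none``, ``noise_pass1``, ``small_cluster_pass1``,
    ``noise_pass2``, ``small_cluster_pass2``.
    """

    table: pd.DataFrame  # columns pass1, final, reason; index = cell ids

    @property
    def final(self) -> pd.Series:
        return self.table["final"]

    @property
    def retained(self) -> pd.Index:
        return self.table.index[self.table["final"] != REMOVED]

    @property
    def n_removed(self) -> int:
        return int((self.table["final"] == REMOVED).sum())

    @property
    def cluster_sizes(self) -> pd.Series:
        labels = self.table.loc[self.table["final"] != REMOVED, "final"]
        return labels.value_counts().sort_index()

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def removed_percent(self, decimals: int = 1) -> float:
        return removed_percent(self.n_removed, len(self.table), decimals)

    def removal_counts(self) -> pd.Series:
        return self.table["reason"].value_counts()


class TwoPassDBSCAN(BaseEstimator, ClusterMixin):
    """Two-pass DBSCAN with size-based pruning.

    Parameters
    ----------
    eps1, eps2:
        Neighborhood radii for the first and second pass.
    min_size1, min_size2:
        Minimum cluster size retained after each pass.
    min_pts:
        DBSCAN ``min_samples`` for both passes.
    """

    def __init__(self, eps1: float = 0.5, min_size1: int = 10,
                 eps2: float = 1.0, min_size2: int = 20, min_pts: int = 10):
        self.eps1 = eps1
        self.min_size1 = min_size1
        self.eps2 = eps2
        self.min_size2 = min_size2
        self.min_pts = min_pts

    def fit(self, X: pd.DataFrame, y=None) -> "TwoPassDBSCAN":
        coords = np.asarray(X, dtype=float)
        n = coords.shape[0]
        if n < self.min_pts:
            raise ValueError(f"need at least min_pts={self.min_pts} cells")
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)

        pass1 = DBSCAN(eps=self.eps1, min_samples=self.min_pts).fit_predict(coords)
        reason = np.full(n, "none", dtype=object)
        reason[pass1 == NOISE] = "noise_pass1"
        sizes1 = pd.Series(pass1[pass1 != NOISE]).value_counts()
        small1 = sizes1.index[sizes1 < self.min_size1]
        reason[np.isin(pass1, small1)] = "small_cluster_pass1"
        survive = reason == "none"
        if not survive.any():
            raise ValueError("pass 1 removed every cell; eps1/min_size1 too "
                             "strict for this embedding")

        pass2 = DBSCAN(eps=self.eps2, min_samples=self.min_pts).fit_predict(
            coords[survive])
        reason2 = reason[survive]
        reason2[pass2 == NOISE] = "noise_pass2"
        sizes2 = pd.Series(pass2[pass2 != NOISE]).value_counts()
        small2 = sizes2.index[sizes2 < self.min_size2]
        reason2[np.isin(pass2, small2)] = "small_cluster_pass2"
        reason[survive] = reason2

        final = np.full(n, REMOVED, dtype=int)
        keep2 = reason2 == "none"
        if not keep2.any():
            raise ValueError("pass 2 removed every cell; eps2/min_size2 too "
                             "strict for this embedding")
        kept_labels = pass2[keep2]
        sizes = pd.Series(kept_labels).value_counts()
        # descending size, ties broken by the original pass-2 label
        order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
        relabel = {old: new for new, old in enumerate(order)}
        final_kept = np.array([relabel[l] for l in kept_labels])
        idx_survive = np.flatnonzero(survive)
        final[idx_survive[keep2]] = final_kept

        self.assignment_ = ClusterAssignment(pd.DataFrame(
            {"pass1": pass1, "final": final, "reason": reason}, index=index))
        self.labels_ = final
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:  # noqa: D102
        return self.fit(X).labels_


def dbscan_two_pass(embedding, eps1: float = 0.5, min_size1: int = 10,
                    eps2: float = 1.0, min_size2: int = 20,
                    min_pts: int = 10) -> ClusterAssignment:
    """Cluster a tSNE embedding; see :class:`TwoPassDBSCAN`.

    ``embedding`` may be an :class:`~scfibro.reduce.Embedding` or a
    coordinate DataFrame.
    """
    coords = getattr(embedding, "coords", embedding)
    model = TwoPassDBSCAN(eps1=eps1, min_size1=min_size1, eps2=eps2,
                          min_size2=min_size2, min_pts=min_pts).fit(coords)
    return model.assignment_


@dataclass
class CompositionTable:
    """Cluster composition across condition labels.

    ``counts``/``proportions`` are cluster x condition; proportions are
    within-condition (each condition column sums to 1). ``tests`` holds
    two-sided two-proportion z-tests for every (cluster, condition pair),
    with BH q-values computed across all tests.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    tests: pd.DataFrame


def composition_by_group(assign: ClusterAssignment,
                         meta: pd.DataFrame) -> CompositionTable:
    """Per-condition cluster composition with pairwise proportion tests."""
    retained = assign.retained
    cond = meta.loc[retained, "condition"]
    labels = assign.final.loc[retained]
    counts = pd.crosstab(labels, cond, dropna=False)
    counts.index.name = "cluster"
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"conditions with no retained cells: {empty}")
    proportions = counts / totals

    rows = []
    conditions = list(counts.columns)
    for cluster in counts.index:
        for i, a in enumerate(conditions):
            for b in conditions[i + 1:]:
                k = np.array([counts.loc[cluster, a], counts.loc[cluster, b]])
                nobs = np.array([totals[a], totals[b]])
                if k.sum() == 0 or (k == nobs).all():
                    p = 1.0
                else:
                    _, p = proportions_ztest(k, nobs, alternative="two-sided")
                rows.append((cluster, a, b, k[0], k[1], p))
    tests = pd.DataFrame(rows, columns=["cluster", "condition_a",
                                        "condition_b", "count_a", "count_b",
                                        "p"])
    if len(tests) and len(conditions) > 1:
        tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    else:
        tests["q"] = np.nan
    return CompositionTable(counts=counts, proportions=proportions,
                            tests=tests)


def subcluster(expr: pd.DataFrame, assign: ClusterAssignment,
               target_cluster: int, seed: int = 0,
               hvg_kwargs: dict | None = None,
               n_pcs: int = 20, perplexity: float = 30.0,
               dbscan_kwargs: dict | None = None) -> ClusterAssignment:
    """Re-run HVG -> PCA -> tSNE -> two-pass DBSCAN on one cluster's cells.

    Labels of the returned assignment are namespaced as strings
    ``"<parent>.<child>"``; parameters can be overridden per stage.
    """
    from .reduce import run_pca, run_tsne, select_hvg

    members = assign.table.index[assign.final == target_cluster]
    if len(members) == 0:
        raise ValueError(f"cluster {target_cluster} does not exist")
    dbscan_kwargs = dict(dbscan_kwargs or {})
    min_pts = dbscan_kwargs.get("min_pts", 10)
    if len(members) < min_pts:
        raise ValueError(f"cluster {target_cluster} has {len(members)} cells, "
                         f"fewer than min_pts={min_pts}")
    sub = expr.loc[members]
    hvg = select_hvg(sub, **(hvg_kwargs or {}))
    genes = hvg.selected if hvg.selected else list(sub.columns)
    n_comp = min(n_pcs, len(genes), len(members) - 1)
    pca = run_pca(sub, genes, n_components=n_comp)
    emb = run_tsne(pca, n_pcs=n_comp, perplexity=perplexity, seed=seed)
    child = dbscan_two_pass(emb, **dbscan_kwargs)
    table = child.table.copy()
    table["final_namespaced"] = [
        f"{target_cluster}.{l}" if l != REMOVED else "removed"
        for l in table["final"]
    ]
    table.attrs["parent_cluster"] = target_cluster
    table.attrs["params"] = {"n_pcs": n_comp, "perplexity": perplexity,
                             "seed": seed, **dbscan_kwargs,
                             **(hvg_kwargs or {})}
    return ClusterAssignment(table)
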