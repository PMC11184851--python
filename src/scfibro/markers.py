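"""Two-stage marker-gene calling with a bimodal likelihood-ratio test.

Single-cell expression of one gene is modeled as a mixture of a point mass
at zero (the gene is not detected) and a normal distribution on the positive
log-normalized values: parameters are the expression fraction ``pi`` and the
positive-part mean and standard deviation. The likelihood-ratio statistic
compares fitting the two groups separately against a pooled fit,

    LR = 2 (LL_a + LL_b - LL_pooled),

and is referred to a chi-square distribution with 3 degrees of freedom (the
three parameters that are allowed to differ). The positive-part standard
deviation is floored at 1e-3 to avoid degenerate likelihoods.

Stage 1 compares each cluster against all other cells (effect threshold on
the difference of mean natural-log expression, BH-corrected p). Stage 2
requires a gene to clear a looser threshold against *every* other cluster
separately (unadjusted p). Markers are the intersection of the two sets.
A post-hoc validity check counts, for every unordered cluster pair, genes
differing by more than a stricter effect threshold at BH-corrected
significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bimod_lrt",
    "bh_fdr",
    "deg_one_vs_rest",
    "deg_pairwise",
    "overlap_markers",
    "posthoc_cluster_validity",
    "top_markers",
    "MarkerCaller",
]

_SD_FLOOR = 1e-3
_LRT_DF = 3


@dataclass
class _GroupStats:
    """Sufficient statistics of the zero-inflated normal, per gene."""

    n: float
    n_pos: np.ndarray
    sum_pos: np.ndarray
    sumsq_pos: np.ndarray
    mean: np.ndarray  # mean over all values, zeros included

    @classmethod
    def from_matrix(cls, X: np.ndarray) -> "_GroupStats":
        pos = X > 0
        vals = np.where(pos, X, 0.0)
        return cls(
            n=float(X.shape[0]),
            n_pos=pos.sum(axis=0).astype(float),
            sum_pos=vals.sum(axis=0),
            sumsq_pos=(vals ** 2).sum(axis=0),
            mean=X.mean(axis=0),
        )

    def __add__(self, other: "_GroupStats") -> "_GroupStats":
        n = self.n + other.n
        return _GroupStats(
            n=n,
            n_pos=self.n_pos + other.n_pos,
            sum_pos=self.sum_pos + other.sum_pos,
            sumsq_pos=self.sumsq_pos + other.sumsq_pos,
            mean=(self.n * self.mean + other.n * other.mean) / n,
        )

    def loglik(self) -> np.ndarray:
        """Maximized log-likelihood of the mixture, per gene."""
        n, k = self.n, self.n_pos
        ll = np.zeros_like(k)
        mixed = (k > 0) & (k < n)
        pi = np.where(mixed, k / n, 0.5)  # placeholder where not mixed
        ll[mixed] = (k[mixed] * np.log(pi[mixed])
                     + (n - k[mixed]) * np.log1p(-pi[mixed]))
        pos = k > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(pos, self.sum_pos / np.where(pos, k, 1.0), 0.0)
            var = np.where(pos, self.sumsq_pos / np.where(pos, k, 1.0)
                           - mu ** 2, 0.0)
        var = np.maximum(var, 0.0)
        sd = np.maximum(np.sqrt(var), _SD_FLOOR)
        ll[pos] += (-k[pos] * np.log(sd[pos] * np.sqrt(2 * np.pi))
                    - k[pos] * var[pos] / (2 * sd[pos] ** 2))
        return ll


def _lrt_genes(a: _GroupStats, b: _GroupStats) -> tuple[np.ndarray, np.ndarray]:
    stat = 2.0 * (a.loglik() + b.loglik() - (a + b).loglik())
    stat = np.maximum(stat, 0.0)
    return stat, scipy.stats.chi2.sf(stat, _LRT_DF)


def bimod_lrt(values_a, values_b) -> tuple[float, float]:
    """Bimodal likelihood-ratio test between two groups of one gene's values.

    Returns ``(statistic, p)``; identical groups give a statistic near 0 and
    p near 1, and two all-zero groups give exactly (0, 1).
    """
    a = np.asarray(values_a, dtype=float).reshape(-1, 1)
    b = np.asarray(values_b, dtype=float).reshape(-1, 1)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = _lrt_genes(_GroupStats.from_matrix(a), _GroupStats.from_matrix(b))
    return float(stat[0]), float(p[0])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cluster_stats(expr: pd.DataFrame,
                   labels: pd.Series) -> dict[int, _GroupStats]:
    """Per-cluster sufficient statistics over retained cells."""
    stats = {}
    for c in sorted(labels.unique()):
        stats[c] = _GroupStats.from_matrix(
            expr.loc[labels.index[labels == c]].to_numpy(dtype=float))
    return stats


def _labels_of(assign) -> pd.Series:
    labels = getattr(assign, "final", assign)
    labels = pd.Series(labels)
    return labels[labels != -1]


def deg_one_vs_rest(expr: pd.DataFrame, assign, min_log_diff: float = 0.5,
                    max_fdr: float = 0.01) -> pd.DataFrame:
    """Stage-1 DEGs: each cluster against all other cells.

    A (gene, cluster) record is kept iff the difference of mean natural-log
    expression is strictly greater than ``min_log_diff`` and the BH q-value
    (computed across genes within the cluster's comparison) is below
    ``max_fdr``. Returns records with columns gene, cluster, avg_log_diff,
    p, q, direction.
    """
    labels = _labels_of(assign)
    stats = _cluster_stats(expr, labels)
    if len(stats) < 2:
        import warnings
        warnings.warn("fewer than 2 clusters; no one-vs-rest DEGs",
                      stacklevel=2)
        return _empty_deg_frame()
    total = None
    for s in stats.values():
        total = s if total is None else total + s
    rows = []
    for c, sc in stats.items():
        rest = _GroupStats(
            n=total.n - sc.n,
            n_pos=total.n_pos - sc.n_pos,
            sum_pos=total.sum_pos - sc.sum_pos,
            sumsq_pos=total.sumsq_pos - sc.sumsq_pos,
            mean=(total.n * total.mean - sc.n * sc.mean) / (total.n - sc.n),
        )
        diff = sc.mean - rest.mean
        _, p = _lrt_genes(sc, rest)
        q = bh_fdr(p)
        keep = (diff > min_log_diff) & (q < max_fdr)
        for gi in np.flatnonzero(keep):
            rows.append((expr.columns[gi], c, diff[gi], p[gi], q[gi], 1))
    return pd.DataFrame(rows, columns=["gene", "cluster", "avg_log_diff",
                                       "p", "q", "direction"])


def _empty_deg_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "cluster", "avg_log_diff", "p", "q",
                                 "direction"])


def deg_pairwise(expr: pd.DataFrame, assign, min_log_diff: float = 0.25,
                 max_p: float = 0.05) -> dict[int, set[str]]:
    """Stage-2 DEGs: genes significant against *every* other cluster.

    A gene enters cluster ``c``'s set iff, for every other cluster, the mean
    log-expression difference is strictly greater than ``min_log_diff`` and
    the unadjusted LRT p is below ``max_p``.
    """
    labels = _labels_of(assign)
    stats = _cluster_stats(expr, labels)
    clusters = sorted(stats)
    if len(clusters) < 2:
        import warnings
        warnings.warn("fewer than 2 clusters; no pairwise DEGs", stacklevel=2)
        return {c: set() for c in clusters}
    out: dict[int, set[str]] = {}
    pair_cache: dict[tuple[int, int], np.ndarray] = {}
    for c in clusters:
        ok = np.ones(expr.shape[1], dtype=bool)
        for o in clusters:
            if o == c:
                continue
            key = (min(c, o), max(c, o))
            if key not in pair_cache:
                pair_cache[key] = _lrt_genes(stats[key[0]], stats[key[1]])[1]
            p = pair_cache[key]
            diff = stats[c].mean - stats[o].mean
            ok &= (diff > min_log_diff) & (p < max_p)
        out[c] = set(expr.columns[ok])
    return out


def overlap_markers(set1: pd.DataFrame,
                    set2: dict[int, set[str]]) -> pd.DataFrame:
    """Marker table: intersection of stage-1 records and stage-2 sets.

    ``set1`` is the stage-1 DEG record frame; ``set2`` maps cluster to its
    stage-2 gene set (both computed on the same clustering). Rows cover the
    union per cluster; stage-2-only genes carry NaN statistics. Sorted by
    cluster then descending effect.
    """
    frames = []
    clusters = sorted(set(set1["cluster"]).union(set2))
    for c in clusters:
        s1 = set1[set1["cluster"] == c].set_index("gene")
        genes2 = set2.get(c, set())
        genes = sorted(set(s1.index) | genes2)
        sub = s1.reindex(genes)
        sub["cluster"] = c
        sub["in_set1"] = sub.index.isin(s1.index)
        sub["in_set2"] = sub.index.isin(genes2)
        frames.append(sub.reset_index().rename(columns={"index": "gene"}))
    if not frames:
        out = _empty_deg_frame()
        out["in_set1"] = out["in_set2"] = out["is_marker"] = []
        return out
    table = pd.concat(frames, ignore_index=True)
    table["is_marker"] = table["in_set1"] & table["in_set2"]
    return table.sort_values(["cluster", "avg_log_diff"],
                             ascending=[True, False],
                             ignore_index=True)


def posthoc_cluster_validity(expr: pd.DataFrame, assign,
                             min_log_diff: float = 1.0,
                             max_fdr: float = 0.01,
                             min_degs: int = 10) -> pd.DataFrame:
    """Count DEGs for every unordered cluster pair (either direction).

    A gene counts for pair (a, b) iff ``|mean log diff| > min_log_diff`` and
    its BH q-value (across genes within the pair) is below ``max_fdr``.
    ``pass`` is true when the count strictly exceeds ``min_degs``.
    """
    labels = _labels_of(assign)
    stats = _cluster_stats(expr, labels)
    clusters = sorted(stats)
    rows = []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            diff = stats[a].mean - stats[b].mean
            _, p = _lrt_genes(stats[a], stats[b])
            q = bh_fdr(p)
            n = int(((np.abs(diff) > min_log_diff) & (q < max_fdr)).sum())
            rows.append((a, b, n, n > min_degs))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "n_degs",
                                       "pass"])


def top_markers(markers: pd.DataFrame, n: int = 10,
                expr: pd.DataFrame | None = None,
                assign=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Top ``n`` markers per cluster by effect size.

    Ties on ``avg_log_diff`` break by smaller q then gene id. When ``expr``
    and a cluster assignment are given, also returns a genes x clusters
    matrix of mean expression suitable for a heatmap.
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    flagged = markers[markers["is_marker"]] if "is_marker" in markers \
        else markers
    picked = (flagged
              .sort_values(["cluster", "avg_log_diff", "q", "gene"],
                           ascending=[True, False, True, True])
              .groupby("cluster", sort=True)
              .head(n)
              .reset_index(drop=True))
    heatmap = None
    if expr is not None and assign is not None:
        labels = _labels_of(assign)
        genes = picked["gene"].drop_duplicates().tolist()
        heatmap = (expr.loc[labels.index, genes]
                   .groupby(labels, observed=True).mean().T)
        heatmap.index.name = "gene"
    return picked, heatmap


class MarkerCaller:
    """One-stop two-stage marker calling.

    ``fit(expr, assign)`` runs stage 1, stage 2, the overlap and the
    post-hoc pair validity; results land in ``set1_``, ``set2_``,
    ``markers_`` and ``validity_``.
    """

    def __init__(self, min_log_diff1: float = 0.5, max_fdr1: float = 0.01,
                 min_log_diff2: float = 0.25, max_p2: float = 0.05,
                 posthoc_log_diff: float = 1.0, posthoc_fdr: float = 0.01,
                 posthoc_min_degs: int = 10):
        self.min_log_diff1 = min_log_diff1
        self.max_fdr1 = max_fdr1
        self.min_log_diff2 = min_log_diff2
        self.max_p2 = max_p2
        self.posthoc_log_diff = posthoc_log_diff
        self.posthoc_fdr = posthoc_fdr
        self.posthoc_min_degs = posthoc_min_degs

    def fit(self, expr: pd.DataFrame, assign) -> "MarkerCaller":
        self.set1_ = deg_one_vs_rest(expr, assign, self.min_log_diff1,
                                     self.max_fdr1)
        self.set2_ = deg_pairwise(expr, assign, self.min_log_diff2,
                                  self.max_p2)
        self.markers_ = overlap_markers(self.set1_, self.set2_)
        self.validity_ = posthoc_cluster_validity(
            expr, assign, self.posthoc_log_diff, self.posthoc_fdr,
            self.posthoc_min_degs)
        return self
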