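"""Highly variable genes, PCA, jackStraw PC significance and tSNE.

HVG selection uses the classic binned-dispersion scheme: genes whose mean
log-normalized expression falls inside a window are placed into equal-width
bins of mean expression; within each bin the dispersion (variance/mean of
the gene's values) is z-scored, and genes with a z-score strictly above the
cutoff are selected.

PC significance follows the jackStraw idea: a small fraction of genes is
permuted across cells, PCA is recomputed, and the squared loadings of the
permuted genes form a per-PC null for gene-PC association. Each real gene
gets an empirical p-value against that null; a PC is scored by a one-sided
binomial test on the number of genes with small empirical p-values, and is
called significant when its Bonferroni-adjusted p-value is below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "HvgResult",
    "PcaResult",
    "Embedding",
    "BinnedDispersionHVG",
    "JackStraw",
    "TSNEEmbedder",
    "select_hvg",
    "run_pca",
    "jackstraw_significant_pcs",
    "run_tsne",
]


@dataclass
class HvgResult:
    """Per-gene statistics and the selected gene list."""

    stats: pd.DataFrame  # mean, dispersion, bin_id, z_score, selected
    selected: list[str]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # cells x K
    loadings: pd.DataFrame  # genes x K, unit-norm columns
    variance_explained: np.ndarray  # length K, non-increasing
    jackstraw_p: np.ndarray | None = None


@dataclass
class Embedding:
    coords: pd.DataFrame  # cells x 2, columns tsne1/tsne2
    params: dict


class BinnedDispersionHVG(BaseEstimator, TransformerMixin):
    """Binned-dispersion highly-variable-gene selector.

    Parameters
    ----------
    n_bins:
        Number of equal-width bins of mean expression (``binning="width"``)
        or equal-occupancy bins (``binning="count"``).
    mean_low, mean_high:
        Inclusive window on mean expression; genes outside it are excluded
        before binning.
    z_cutoff:
        A gene is selected iff its within-bin dispersion z-score is strictly
        greater than this.
    """

    def __init__(self, n_bins: int = 20, mean_low: float = 0.0125,
                 mean_high: float = 0.3, z_cutoff: float = 0.5,
                 binning: str = "width"):
        self.n_bins = n_bins
        self.mean_low = mean_low
        self.mean_high = mean_high
        self.z_cutoff = z_cutoff
        self.binning = binning

    def fit(self, X: pd.DataFrame, y=None) -> "BinnedDispersionHVG":
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.binning not in ("width", "count"):
            raise ValueError("binning must be 'width' or 'count'")
        vals = X.to_numpy(dtype=float)
        mean = vals.mean(axis=0)
        var = vals.var(axis=0, ddof=1) if vals.shape[0] > 1 \
            else np.zeros(vals.shape[1])
        stats = pd.DataFrame({"mean": mean}, index=X.columns)
        in_window = (mean >= self.mean_low) & (mean <= self.mean_high)
        with np.errstate(divide="ignore", invalid="ignore"):
            dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0),
                                  0.0)
        stats["dispersion"] = dispersion
        bin_id = np.zeros(len(mean), dtype=int)  # 0 = outside window
        m = mean[in_window]
        if m.size:
            if self.binning == "width":
                edges = np.linspace(m.min(), m.max(), self.n_bins + 1)
            else:
                edges = np.quantile(m, np.linspace(0, 1, self.n_bins + 1))
            # right-inclusive last edge so the max lands in the top bin
            ids = np.clip(np.digitize(m, edges[1:-1], right=False) + 1,
                          1, self.n_bins)
            bin_id[in_window] = ids
        stats["bin_id"] = bin_id
        z = np.zeros(len(mean))
        for b in range(1, self.n_bins + 1):
            members = bin_id == b
            n = int(members.sum())
            if n >= 2:
                d = dispersion[members]
                sd = d.std(ddof=1)
                if sd > 0:
                    z[members] = (d - d.mean()) / sd
            # single-gene bins keep z = 0 by convention
        stats["z_score"] = z
        stats["selected"] = in_window & (z > self.z_cutoff)
        self.stats_ = stats
        self.selected_genes_ = stats.index[stats["selected"]].tolist()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_genes_]

    def result_(self) -> HvgResult:
        return HvgResult(stats=self.stats_, selected=self.selected_genes_)


def select_hvg(expr: pd.DataFrame, n_bins: int = 20, mean_low: float = 0.0125,
               mean_high: float = 0.3, z_cutoff: float = 0.5,
               binning: str = "width") -> HvgResult:
    """Select highly variable genes; see :class:`BinnedDispersionHVG`."""
    sel = BinnedDispersionHVG(n_bins=n_bins, mean_low=mean_low,
                              mean_high=mean_high, z_cutoff=z_cutoff,
                              binning=binning).fit(expr)
    return sel.result_()


def run_pca(expr: pd.DataFrame, genes: list[str] | None = None,
            n_components: int = 20, svd_solver: str = "full",
            random_state: int = 0) -> PcaResult:
    """Column-centered SVD-based PCA on the given genes.

    Deterministic up to sign (scikit-learn's sign convention makes it fully
    deterministic for the ``full`` solver).
    """
    X = expr if genes is None else expr[list(genes)]
    n_max = min(X.shape)
    if n_components > n_max:
        raise ValueError(f"n_components={n_components} exceeds "
                         f"min(cells, genes)={n_max}")
    pca = PCA(n_components=n_components, svd_solver=svd_solver,
              random_state=random_state)
    scores = pca.fit_transform(X.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        loadings=pd.DataFrame(pca.components_.T, index=X.columns, columns=cols),
        variance_explained=pca.explained_variance_.copy(),
    )


class JackStraw(BaseEstimator):
    """jackStraw significance of principal components.

    ``fit(X)`` runs PCA on the (cells x genes) expression slice, then for
    each of ``n_reps`` replicates permutes a random ``prop_permuted``
    fraction of genes across cells, recomputes PCA and pools the permuted
    genes' squared loadings as the per-PC null. Fitted attributes:

    ``pc_pvalues_`` : Bonferroni-unadjusted per-PC p-values (binomial test
    on the count of genes whose empirical p against the null is below
    ``gene_p_threshold``).
    ``significant_pcs_`` : 1-based indices of PCs with Bonferroni-adjusted
    p < ``alpha``.
    """

    def __init__(self, n_test_pcs: int = 30, n_reps: int = 200,
                 prop_permuted: float = 0.01, alpha: float = 0.05,
                 gene_p_threshold: float = 0.05, random_state: int = 0):
        self.n_test_pcs = n_test_pcs
        self.n_reps = n_reps
        self.prop_permuted = prop_permuted
        self.alpha = alpha
        self.gene_p_threshold = gene_p_threshold
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "JackStraw":
        if self.n_reps < 50:
            raise ValueError("n_reps must be >= 50 for a usable null")
        rng = np.random.default_rng(self.random_state)
        vals = np.asarray(X, dtype=float)
        n_cells, n_genes = vals.shape
        k = min(self.n_test_pcs, n_cells - 1, n_genes)
        if np.allclose(vals, vals[0]):
            self.pc_pvalues_ = np.ones(k)
            self.significant_pcs_ = []
            return self

        def loadings(mat: np.ndarray) -> np.ndarray:
            pca = PCA(n_components=k, svd_solver="randomized",
                      random_state=int(rng.integers(2**31 - 1)))
            pca.fit(mat)
            return pca.components_.T  # genes x k

        obs = loadings(vals) ** 2
        n_perm_genes = max(1, int(round(self.prop_permuted * n_genes)))
        null = np.empty((self.n_reps * n_perm_genes, k))
        for rep in range(self.n_reps):
            genes = rng.choice(n_genes, size=n_perm_genes, replace=False)
            perturbed = vals.copy()
            for g in genes:
                perturbed[:, g] = vals[rng.permutation(n_cells), g]
            null[rep * n_perm_genes:(rep + 1) * n_perm_genes] = \
                loadings(perturbed)[genes] ** 2

        # empirical gene p-values per PC, then a one-sided binomial test on
        # the excess of small p-values
        null_sorted = np.sort(null, axis=0)
        n_null = null.shape[0]
        pcs_p = np.empty(k)
        for j in range(k):
            ge = n_null - np.searchsorted(null_sorted[:, j], obs[:, j],
                                          side="right")
            gene_p = (1.0 + ge) / (n_null + 1.0)
            hits = int((gene_p <= self.gene_p_threshold).sum())
            pcs_p[j] = scipy.stats.binom.sf(hits - 1, n_genes,
                                            self.gene_p_threshold)
        self.pc_pvalues_ = pcs_p
        adjusted = np.minimum(pcs_p * k, 1.0)
        self.significant_pcs_ = [j + 1 for j in range(k)
                                 if adjusted[j] < self.alpha]
        return self


def jackstraw_significant_pcs(
    expr: pd.DataFrame, genes: list[str] | None = None,
    n_test_pcs: int = 30, n_reps: int = 200, prop_permuted: float = 0.01,
    alpha: float = 0.05, seed: int = 0,
) -> list[int]:
    """1-based indices of jackStraw-significant PCs; see :class:`JackStraw`."""
    X = expr if genes is None else expr[list(genes)]
    js = JackStraw(n_test_pcs=n_test_pcs, n_reps=n_reps,
                   prop_permuted=prop_permuted, alpha=alpha,
                   random_state=seed).fit(X)
    return js.significant_pcs_


class TSNEEmbedder(BaseEstimator):
    """Two-dimensional tSNE of the leading PC scores.

    Raw tSNE coordinates have an arbitrary, implementation- and size-
    dependent scale, which would make any fixed density radius downstream
    meaningless. The embedding is therefore standardized to a canonical
    scale: after centering, coordinates are rescaled so the root-mean-square
    radius equals ``embed_scale * sqrt(n_cells)``. Growing the map radius
    with sqrt(n) keeps the within-cluster point density roughly constant
    across dataset sizes, so a fixed DBSCAN eps keeps its meaning. Set
    ``embed_scale=None`` for raw coordinates.
    """

    def __init__(self, n_pcs: int = 20, perplexity: float = 30.0,
                 random_state: int = 0, embed_scale: float | None = 1 / 5):
        self.n_pcs = n_pcs
        self.perplexity = perplexity
        self.random_state = random_state
        self.embed_scale = embed_scale

    def fit(self, X: pd.DataFrame, y=None) -> "TSNEEmbedder":
        n = X.shape[0]
        if self.perplexity >= (n - 1) / 3:
            raise ValueError(
                f"perplexity={self.perplexity} too large for {n} cells; "
                f"needs perplexity < (cells-1)/3 = {(n - 1) / 3:.1f}")
        if self.n_pcs > X.shape[1]:
            raise ValueError(f"n_pcs={self.n_pcs} exceeds available "
                             f"components ({X.shape[1]})")
        sub = np.asarray(X, dtype=float)[:, : self.n_pcs]
        tsne = TSNE(n_components=2, perplexity=self.perplexity,
                    init="pca", learning_rate="auto",
                    random_state=self.random_state)
        coords = tsne.fit_transform(sub).astype(float)
        if self.embed_scale is not None:
            coords = coords - coords.mean(axis=0)
            rms = float(np.sqrt((coords ** 2).sum(axis=1).mean()))
            if rms > 0:
                coords *= self.embed_scale * np.sqrt(n) / rms
        self.embedding_ = pd.DataFrame(coords, index=X.index,
                                       columns=["tsne1", "tsne2"])
        return self


def run_tsne(pca: PcaResult, n_pcs: int = 20, perplexity: float = 30.0,
             seed: int = 0) -> Embedding:
    """Embed the leading ``n_pcs`` PC scores in 2-D with tSNE."""
    emb = TSNEEmbedder(n_pcs=n_pcs, perplexity=perplexity,
                       random_state=seed).fit(pca.scores)
    return Embedding(coords=emb.embedding_,
                     params={"n_pcs": n_pcs, "perplexity": perplexity,
                             "seed": seed})
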