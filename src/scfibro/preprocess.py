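"""Quality control and normalization.

The stages, in the order a run applies them:

1. :class:`QCFilter` — drop cells with fewer than ``min_genes`` or more than
   ``max_genes`` detected genes (strict inequalities; boundary cells are
   kept), or with a mitochondrial count fraction strictly above ``max_mito``;
   then drop genes detected in fewer than ``min_cells_per_gene`` of the
   surviving cells. All cell rules are evaluated on the raw matrix.
2. :class:`LogNormalizer` — ``ln(1 + count * scale_factor / total_umi)``,
   i.e. depth-normalize every cell to ``scale_factor`` molecules and take
   the natural log.
3. :class:`UMICovariateRegressor` — per gene, replace values by ordinary
   least-squares residuals of expression on the cell's total UMI count
   (with intercept), plus the gene's grand mean so values keep their scale.
4. :class:`BatchMeanCorrector` — per gene, equalize batch means by
   subtracting the batch offset estimated by least squares on batch
   indicators, preserving the grand mean.

Each estimator follows the scikit-learn protocol (``fit`` / ``transform``,
parameters in ``__init__``, fitted attributes with trailing underscores) and
accepts/returns cells x genes ``pandas.DataFrame`` objects. The module-level
functions are thin one-call wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "QcReport",
    "QCFilter",
    "LogNormalizer",
    "UMICovariateRegressor",
    "BatchMeanCorrector",
    "compute_cell_metadata",
    "filter_cells_genes",
    "normalize_log",
    "regress_out_umi",
    "correct_batch",
]

MITO_PREFIXES = ("mt-", "Mt-", "MT-")


@dataclass
class QcReport:
    """Removal accounting for one filtering pass.

    Cells violating several rules are attributed to the first matching rule
    in the order low-gene, high-gene, high-mito, so the per-rule counts sum
    exactly to ``n_cells_in - n_cells_out``.
    """

    n_cells_in: int = 0
    n_cells_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    removed_low_gene_cells: int = 0
    removed_high_gene_cells: int = 0
    removed_high_mito_cells: int = 0
    removed_low_prevalence_genes: int = 0

    def reconciles(self) -> bool:
        cells_ok = (self.removed_low_gene_cells + self.removed_high_gene_cells
                    + self.removed_high_mito_cells
                    == self.n_cells_in - self.n_cells_out)
        genes_ok = (self.removed_low_prevalence_genes
                    == self.n_genes_in - self.n_genes_out)
        return cells_ok and genes_ok

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": [getattr(self, f.name) for f in
                       self.__dataclass_fields__.values()]},
            index=list(self.__dataclass_fields__),
        )


def _mito_genes(gene_ids: pd.Index, mito_genes: Sequence[str] | None,
                mito_prefixes: Sequence[str]) -> pd.Index:
    if mito_genes is not None:
        missing = set(mito_genes) - set(gene_ids)
        if missing:
            raise ValueError(f"mito_genes not in matrix: {sorted(missing)[:5]}")
        return pd.Index(mito_genes)
    return gene_ids[gene_ids.str.startswith(tuple(mito_prefixes))]


def compute_cell_metadata(
    counts: pd.DataFrame,
    mito_genes: Sequence[str] | None = None,
    mito_prefixes: Sequence[str] = MITO_PREFIXES,
) -> pd.DataFrame:
    """Per-cell totals, detected-gene counts and mitochondrial fraction,
    all computed on raw counts."""
    mito = _mito_genes(counts.columns, mito_genes, mito_prefixes)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mito_frac = counts[mito].sum(axis=1) / total.replace(0, np.nan)
    return pd.DataFrame(
        {
            "total_umi": total.astype(int),
            "n_genes_detected": (counts > 0).sum(axis=1).astype(int),
            "mito_fraction": mito_frac.fillna(0.0),
        },
        index=counts.index,
    )


class QCFilter(BaseEstimator, TransformerMixin):
    """Cell and gene quality filter.

    Parameters
    ----------
    min_genes, max_genes:
        A cell is removed when its number of detected genes is strictly
        below ``min_genes`` or strictly above ``max_genes``.
    min_cells_per_gene:
        Genes detected in fewer than this many surviving cells are removed.
    max_mito:
        Cells with mitochondrial count fraction strictly above this are
        removed.
    mito_genes, mito_prefixes:
        Explicit mitochondrial gene list, or (default) a prefix match.
    """

    def __init__(self, min_genes: int = 200, max_genes: int = 3000,
                 min_cells_per_gene: int = 10, max_mito: float = 0.5,
                 mito_genes: Sequence[str] | None = None,
                 mito_prefixes: Sequence[str] = MITO_PREFIXES):
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.min_cells_per_gene = min_cells_per_gene
        self.max_mito = max_mito
        self.mito_genes = mito_genes
        self.mito_prefixes = mito_prefixes

    def fit(self, X: pd.DataFrame, y=None) -> "QCFilter":
        if self.min_genes <= 0 or self.max_genes <= 0 \
                or self.min_cells_per_gene <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        meta = compute_cell_metadata(X, self.mito_genes, self.mito_prefixes)
        low = meta["n_genes_detected"] < self.min_genes
        high = ~low & (meta["n_genes_detected"] > self.max_genes)
        mito = ~low & ~high & (meta["mito_fraction"] > self.max_mito)
        keep_cells = ~(low | high | mito)
        if not keep_cells.any():
            raise ValueError("QC removed every cell; thresholds too strict "
                             "for this matrix")
        prevalence = (X.loc[keep_cells] > 0).sum(axis=0)
        keep_genes = prevalence >= self.min_cells_per_gene
        self.cell_mask_ = keep_cells
        self.gene_mask_ = keep_genes
        self.cell_metadata_ = meta
        self.report_ = QcReport(
            n_cells_in=X.shape[0],
            n_cells_out=int(keep_cells.sum()),
            n_genes_in=X.shape[1],
            n_genes_out=int(keep_genes.sum()),
            removed_low_gene_cells=int(low.sum()),
            removed_high_gene_cells=int(high.sum()),
            removed_high_mito_cells=int(mito.sum()),
            removed_low_prevalence_genes=int((~keep_genes).sum()),
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[self.cell_mask_, self.gene_mask_]


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Depth normalization to ``scale_factor`` molecules per cell followed
    by ``ln(1 + x)``. Stateless apart from recording the raw totals."""

    def __init__(self, scale_factor: float = 1e4):
        self.scale_factor = scale_factor

    def fit(self, X: pd.DataFrame, y=None) -> "LogNormalizer":
        totals = X.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValueError(
                f"cell {bad!r} has zero total counts; filter cells first")
        self.total_umi_ = totals.astype(float)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        totals = X.sum(axis=1).astype(float)
        values = np.log1p(X.to_numpy(dtype=float)
                          * (self.scale_factor / totals.to_numpy())[:, None])
        out = pd.DataFrame(values, index=X.index, columns=X.columns)
        out.attrs["normalized"] = True
        out.attrs["scale_factor"] = self.scale_factor
        return out


class UMICovariateRegressor(BaseEstimator, TransformerMixin):
    """Per-gene OLS residualization on the total UMI count.

    ``fit(X, total_umi=...)`` estimates per-gene slopes on the centered
    covariate; ``transform`` subtracts the fitted linear component, leaving
    residuals (uncorrelated with the covariate) plus the gene's grand mean.
    A constant covariate degenerates to the identity with a warning.
    """

    def fit(self, X: pd.DataFrame, y=None, *,
            total_umi: pd.Series | np.ndarray) -> "UMICovariateRegressor":
        u = np.asarray(total_umi, dtype=float)
        if u.shape[0] != X.shape[0]:
            raise ValueError("total_umi length must match the cell count")
        uc = u - u.mean()
        denom = float(uc @ uc)
        if denom == 0.0:
            warnings.warn("total UMI is constant across cells; UMI "
                          "regression is the identity", stacklevel=2)
            self.slope_ = pd.Series(0.0, index=X.columns)
        else:
            vals = X.to_numpy(dtype=float)
            self.slope_ = pd.Series(uc @ vals / denom, index=X.columns)
        self.umi_mean_ = float(u.mean())
        return self

    def transform(self, X: pd.DataFrame, *,
                  total_umi: pd.Series | np.ndarray) -> pd.DataFrame:
        u = np.asarray(total_umi, dtype=float) - self.umi_mean_
        vals = X.to_numpy(dtype=float) - np.outer(u, self.slope_.to_numpy())
        out = pd.DataFrame(vals, index=X.index, columns=X.columns)
        out.attrs.update(X.attrs)
        out.attrs["umi_regressed"] = True
        return out

    def fit_transform(self, X, y=None, **kwargs):  # noqa: D102
        return self.fit(X, **kwargs).transform(X, **kwargs)


class BatchMeanCorrector(BaseEstimator, TransformerMixin):
    """Per-gene batch-mean equalization on the log scale.

    The offset of each batch from the grand mean is estimated by least
    squares on batch indicators (equivalently, batch means of each gene) and
    subtracted, so per-gene batch means coincide afterwards. Applying the
    transform twice equals applying it once.
    """

    def fit(self, X: pd.DataFrame, y=None, *,
            batch: pd.Series | Sequence) -> "BatchMeanCorrector":
        batch = pd.Series(np.asarray(batch, dtype=object), index=X.index)
        sizes = batch.value_counts()
        if (sizes < 2).any():
            small = sizes.index[sizes < 2].tolist()
            warnings.warn(f"batches with fewer than 2 cells: {small}; "
                          "offsets still estimated", stacklevel=2)
        grand = X.mean(axis=0)
        self.offsets_ = X.groupby(batch, observed=True).mean() - grand
        return self

    def transform(self, X: pd.DataFrame, *,
                  batch: pd.Series | Sequence) -> pd.DataFrame:
        batch = pd.Series(np.asarray(batch, dtype=object), index=X.index)
        offs = self.offsets_.reindex(batch.to_numpy()).to_numpy()
        out = pd.DataFrame(X.to_numpy(dtype=float) - offs,
                           index=X.index, columns=X.columns)
        out.attrs.update(X.attrs)
        out.attrs["batch_corrected"] = True
        return out

    def fit_transform(self, X, y=None, **kwargs):  # noqa: D102
        return self.fit(X, **kwargs).transform(X, **kwargs)


# ---------------------------------------------------------------------------
# functional wrappers

def filter_cells_genes(
    counts: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 3000,
    min_cells_per_gene: int = 10,
    max_mito: float = 0.5,
    mito_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the QC filter once; returns the filtered matrix and a report."""
    qc = QCFilter(min_genes=min_genes, max_genes=max_genes,
                  min_cells_per_gene=min_cells_per_gene, max_mito=max_mito,
                  mito_genes=mito_genes).fit(counts)
    return qc.transform(counts), qc.report_


def normalize_log(counts: pd.DataFrame,
                  scale_factor: float = 1e4) -> pd.DataFrame:
    """Log-normalize raw counts; see :class:`LogNormalizer`."""
    return LogNormalizer(scale_factor=scale_factor).fit_transform(counts)


def regress_out_umi(expr: pd.DataFrame,
                    total_umi: pd.Series | np.ndarray) -> pd.DataFrame:
    """Residualize expression on total UMI; see :class:`UMICovariateRegressor`."""
    return UMICovariateRegressor().fit_transform(expr, total_umi=total_umi)


def correct_batch(expr: pd.DataFrame,
                  batch: pd.Series | Sequence) -> pd.DataFrame:
    """Equalize per-gene batch means; see :class:`BatchMeanCorrector`."""
    return BatchMeanCorrector().fit_transform(expr, batch=batch)
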