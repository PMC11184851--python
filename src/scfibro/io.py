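"""Readers and writers for counts, labels and ligand-receptor tables.

Counts travel as Matrix-Market coordinate files (1-based indices) with
sidecar ``cells.tsv`` / ``genes.tsv`` label files, or as a dense TSV with
cell ids in the first column and gene ids in the header. In memory a count
matrix is a cells x genes integer ``pandas.DataFrame``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["read_counts", "write_counts", "load_lr_database", "FormatError"]


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


def _read_labels(path: Path, what: str) -> list[str]:
    if not path.is_file():
        raise FormatError(f"missing {what} label file: {path}")
    labels = pd.read_csv(path, sep="\t")
    col = labels.columns[0]
    values = labels[col].astype(str).tolist()
    if len(set(values)) != len(values):
        raise FormatError(f"duplicate {what} identifiers in {path}")
    return values


def read_counts(
    path: str | Path,
    format: str = "mtx",
    cells_path: str | Path | None = None,
    genes_path: str | Path | None = None,
    genes_as_rows: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a count matrix; returns ``(counts, metadata_skeleton)``.

    Parameters
    ----------
    path:
        The matrix file (``.mtx`` coordinate triplets or dense TSV).
    format:
        ``"mtx"`` or ``"tsv"``.
    cells_path, genes_path:
        Label files for the mtx format; default to ``cells.tsv`` /
        ``genes.tsv`` next to the matrix.
    genes_as_rows:
        Set when the on-disk matrix is genes x cells; the returned frame is
        always cells x genes.

    The metadata skeleton holds per-cell ``total_umi`` and
    ``n_genes_detected`` computed from the raw counts.
    """
    path = Path(path)
    if format == "mtx":
        cells_path = Path(cells_path) if cells_path else path.parent / "cells.tsv"
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cell_ids = _read_labels(cells_path, "cell")
        gene_ids = _read_labels(genes_path, "gene")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise FormatError(f"cannot parse Matrix-Market file {path}: {exc}")
        dense = sp.coo_matrix(mat).toarray()
        if genes_as_rows:
            dense = dense.T
        if dense.shape != (len(cell_ids), len(gene_ids)):
            raise FormatError(
                f"{path}: matrix shape {dense.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes")
        counts = pd.DataFrame(dense, index=cell_ids, columns=gene_ids)
    elif format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if genes_as_rows:
            counts = counts.T
        if counts.index.duplicated().any() or counts.columns.duplicated().any():
            raise FormatError(f"{path}: duplicate cell or gene identifiers")
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx' or 'tsv'")

    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    counts = counts.astype(int)
    counts.index.name = "cell_id"
    meta = pd.DataFrame(
        {
            "total_umi": counts.sum(axis=1),
            "n_genes_detected": (counts > 0).sum(axis=1),
        },
        index=counts.index,
    )
    return counts, meta


def write_counts(counts: pd.DataFrame, path: str | Path,
                 format: str = "mtx") -> None:
    """Write a cells x genes count matrix (mtx + label sidecars, or TSV)."""
    path = Path(path)
    if format == "mtx":
        scipy.io.mmwrite(path, sp.coo_matrix(counts.to_numpy()), field="integer")
        pd.Series(counts.index).to_csv(path.parent / "cells.tsv", sep="\t",
                                       index=False, header=["cell_id"])
        pd.Series(counts.columns).to_csv(path.parent / "genes.tsv", sep="\t",
                                         index=False, header=["gene_id"])
    elif format == "tsv":
        counts.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx' or 'tsv'")


def load_lr_database(path: str | Path) -> pd.DataFrame:
    """Load a ligand-receptor pair table (TSV with a header row).

    The first two columns are ligand and receptor gene ids; any third column
    is kept as an annotation. Duplicate pairs are dropped with a warning.
    Genes absent from an expression matrix are flagged at scoring time.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: need at least two columns (ligand, receptor)")
    table = table.rename(columns={table.columns[0]: "ligand",
                                  table.columns[1]: "receptor"})
    for i, row in enumerate(table.itertuples(index=False), start=2):
        if not row.ligand or pd.isna(row.ligand) \
                or not row.receptor or pd.isna(row.receptor):
            raise FormatError(f"{path}: malformed row at line {i}")
    if "annotation" not in table.columns:
        table["annotation"] = ""
    dup = table.duplicated(subset=["ligand", "receptor"])
    if dup.any():
        warnings.warn(f"{path}: dropped {int(dup.sum())} duplicate "
                      "ligand-receptor pairs", stacklevel=2)
        table = table[~dup]
    return table[["ligand", "receptor", "annotation"]].reset_index(drop=True)
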