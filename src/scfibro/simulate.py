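"""Synthetic single-cell count data with planted structure.

The generator emulates a droplet-style kidney scRNA-seq experiment: a
cell x gene matrix of negative-binomial UMI counts with

* several cell populations, each carrying a disjoint block of marker genes
  whose negative-binomial mean is shifted upward on the natural-log scale,
* per-cell library-size variation (log-normal depth factors),
* a small set of highly expressed mitochondrial genes (``mt-`` prefix),
* a fraction of low-quality cells, implemented either as binomial thinning
  (few detected genes) or mitochondrial inflation (high mito fraction),
* a gene-wise additive batch offset on the log scale,
* condition labels with optional per-condition population-weight overrides,
* planted ligand-receptor programs: the ligand mean is raised in a sender
  population and the receptor mean in a receiver population.

Everything planted is recorded in a :class:`GroundTruth` so downstream
stages can be scored against a known answer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "LrProgram",
    "GeneratorConfig",
    "GroundTruth",
    "generate_counts",
    "write_fixture",
    "read_fixture",
    "make_lr_database",
]

_MITO_BOOST = 20.0  # multiplier on baseline mean for mitochondrial genes
_MITO_SIGMA = 0.5  # log-normal sd of mito baselines (uniformly high genes)
_MITO_NB_SIZE = 5.0  # mito genes are much less overdispersed than average
_MITO_INFLATION = 60.0  # extra multiplier for mito-driven low-quality cells
_THINNING_KEEP = 0.05  # binomial keep probability for thinned low-quality cells


@dataclass(frozen=True)
class LrProgram:
    """A planted ligand-receptor co-expression program.

    ``ligand``/``receptor`` may be gene ids or ``None`` (auto-assigned to
    unused non-marker genes at generation time). ``sender``/``receiver`` are
    population indices; ``log_shift`` is the natural-log increase of the
    ligand mean in the sender and the receptor mean in the receiver.
    """

    ligand: str | None = None
    receptor: str | None = None
    sender: int = 0
    receiver: int = 1
    log_shift: float = 2.0


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    Defaults describe the standing study conditions: 3,000 cells, 2,000
    genes, 12 equally weighted populations with 50 disjoint markers each at
    a +2.0 natural-log shift, NB size 0.5, three condition labels, two
    batches and 5% low-quality cells.
    """

    n_cells: int = 3000
    n_genes: int = 2000
    n_populations: int = 12
    population_weights: Sequence[float] | None = None
    markers_per_population: int = 50
    n_marked_populations: int | None = None
    marker_log_shift: float = 2.0
    baseline_mean: float = 0.5
    baseline_sigma: float = 1.5
    marker_baseline_band: tuple[float, float] = (0.22, 0.34)
    marker_strong_fraction: float = 0.2
    marker_strong_band: tuple[float, float] = (0.8, 1.5)
    nb_dispersion: float = 0.5
    libsize_sigma: float = 0.2
    n_mito_genes: int = 13
    frac_low_quality: float = 0.05
    n_batches: int = 2
    batch_log_offset: float = 0.3
    conditions: Sequence[str] = ("Normal", "DKD", "MSC-sEV")
    condition_weights: Mapping[str, Sequence[float]] | None = None
    lr_programs: Sequence[LrProgram] | None = None
    seed: int = 0

    def resolved_weights(self) -> np.ndarray:
        if self.population_weights is None:
            return np.full(self.n_populations, 1.0 / self.n_populations)
        w = np.asarray(self.population_weights, dtype=float)
        return w

    def validate(self) -> None:
        def bad(name: str, why: str) -> ValueError:
            return ValueError(f"invalid GeneratorConfig.{name}: {why}")

        if self.n_cells < 1:
            raise bad("n_cells", "must be >= 1")
        if self.n_genes < 1:
            raise bad("n_genes", "must be >= 1")
        if self.n_populations < 1:
            raise bad("n_populations", "must be >= 1")
        w = self.resolved_weights()
        if w.shape != (self.n_populations,):
            raise bad("population_weights", "length must equal n_populations")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise bad("population_weights", "must be non-negative and sum to 1")
        n_marked = self.n_marked_populations
        if n_marked is not None and not 0 <= n_marked <= self.n_populations:
            raise bad("n_marked_populations", "must be in [0, n_populations]")
        if self.markers_per_population < 0:
            raise bad("markers_per_population", "must be >= 0")
        n_marked = self.n_populations if n_marked is None else n_marked
        n_reserved = self.n_mito_genes + n_marked * self.markers_per_population
        if n_reserved > self.n_genes:
            raise bad("markers_per_population",
                      f"{n_reserved} reserved genes exceed n_genes={self.n_genes}")
        for name in ("baseline_mean", "baseline_sigma", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise bad(name, "must be > 0")
        for name in ("marker_baseline_band", "marker_strong_band"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise bad(name, "need 0 < low <= high")
        if not 0 <= self.marker_strong_fraction <= 1:
            raise bad("marker_strong_fraction", "must be in [0, 1]")
        if self.libsize_sigma < 0:
            raise bad("libsize_sigma", "must be >= 0")
        if self.n_mito_genes < 0:
            raise bad("n_mito_genes", "must be >= 0")
        if not 0 <= self.frac_low_quality < 0.5:
            raise bad("frac_low_quality", "must be in [0, 0.5)")
        if self.n_batches < 1:
            raise bad("n_batches", "must be >= 1")
        if len(self.conditions) < 1:
            raise bad("conditions", "need at least one condition label")
        if self.condition_weights is not None:
            for label, cw in self.condition_weights.items():
                if label not in self.conditions:
                    raise bad("condition_weights", f"unknown condition {label!r}")
                cw = np.asarray(cw, dtype=float)
                if cw.shape != (self.n_populations,) or np.any(cw < 0) \
                        or not np.isclose(cw.sum(), 1.0):
                    raise bad("condition_weights",
                              f"weights for {label!r} must be a probability "
                              f"vector of length n_populations")
        for i, prog in enumerate(self.lr_programs or ()):
            if not (0 <= prog.sender < self.n_populations
                    and 0 <= prog.receiver < self.n_populations):
                raise bad("lr_programs", f"program {i}: population index out of range")


@dataclass
class GroundTruth:
    """Everything planted by :func:`generate_counts`."""

    population: pd.Series  # cell -> population index
    condition: pd.Series
    batch: pd.Series
    low_quality: pd.Series  # cell -> {"", "thinned", "mito"}
    marker_genes: dict[int, list[str]]  # population -> marker gene ids
    mito_genes: list[str]
    batch_affected_genes: list[str]
    lr_pairs: pd.DataFrame  # ligand, receptor, sender, receiver, log_shift

    def marker_of(self) -> pd.Series:
        """Gene id -> population index for all planted marker genes."""
        pairs = [(g, p) for p, genes in self.marker_genes.items() for g in genes]
        if not pairs:
            return pd.Series(dtype=int)
        genes, pops = zip(*pairs)
        return pd.Series(pops, index=list(genes), name="population")


def generate_counts(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a synthetic count matrix.

    Returns ``(counts, metadata, truth)`` where ``counts`` is a cells x genes
    integer DataFrame, ``metadata`` has columns ``condition`` and ``batch``
    indexed by cell id, and ``truth`` records the planted structure. The same
    config (including seed) always yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cells, n_genes = config.n_cells, config.n_genes
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    gene_ids = [f"mt-{i + 1}" for i in range(config.n_mito_genes)]
    gene_ids += [f"gene{i:05d}" for i in range(n_genes - config.n_mito_genes)]

    # per-gene baseline NB means, log-normal around baseline_mean
    base = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_sigma, size=n_genes))
    mito_idx = np.arange(config.n_mito_genes)
    # mitochondrial genes: uniformly high and tight, like real mt transcripts
    base[mito_idx] = config.baseline_mean * _MITO_BOOST * np.exp(
        rng.normal(0.0, _MITO_SIGMA, size=config.n_mito_genes))

    # disjoint marker blocks drawn from non-mitochondrial genes
    n_marked = (config.n_populations if config.n_marked_populations is None
                else config.n_marked_populations)
    candidates = rng.permutation(np.arange(config.n_mito_genes, n_genes))
    marker_genes: dict[int, list[str]] = {}
    marker_idx: dict[int, np.ndarray] = {}
    cursor = 0
    for p in range(n_marked):
        block = np.sort(candidates[cursor:cursor + config.markers_per_population])
        cursor += config.markers_per_population
        marker_idx[p] = block
        marker_genes[p] = [gene_ids[i] for i in block]

    # Marker baselines follow a two-regime design. Most markers sit in a
    # moderate band just below the dispersion-window mean ceiling, where the
    # planted shift produces the largest selectable variance signal; a
    # strong-baseline fraction sits high enough that the shift realizes a
    # >1 natural-log expression difference, which the moderate band cannot
    # reach once library-size normalization compresses low counts.
    for idx in marker_idx.values():
        n_strong = int(round(config.marker_strong_fraction * idx.size))
        strong = rng.choice(idx, size=n_strong, replace=False)
        moderate = np.setdiff1d(idx, strong)
        for sub, (lo, hi) in ((moderate, config.marker_baseline_band),
                              (strong, config.marker_strong_band)):
            base[sub] = config.baseline_mean * np.exp(
                rng.uniform(np.log(lo), np.log(hi), size=sub.size))

    # ligand/receptor genes: auto-pick from the remaining unplanted pool
    pool = list(candidates[cursor:])
    programs: list[LrProgram] = []
    for prog in (config.lr_programs or ()):
        lig, rec = prog.ligand, prog.receptor
        if lig is None:
            lig = gene_ids[pool.pop()]
        if rec is None:
            rec = gene_ids[pool.pop()]
        programs.append(dataclasses.replace(prog, ligand=lig, receptor=rec))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for prog in programs:
        for g in (prog.ligand, prog.receptor):
            if g not in gene_pos:
                raise ValueError(f"lr_programs references unknown gene {g!r}")
            # ligand/receptor transcripts sit in the same moderate band so
            # the detection filter downstream is meaningful
            base[gene_pos[g]] = config.baseline_mean * 0.8

    # cell-level assignments
    condition = rng.choice(len(config.conditions), size=n_cells)
    weights = config.resolved_weights()
    cond_weights = np.tile(weights, (len(config.conditions), 1))
    if config.condition_weights:
        for label, cw in config.condition_weights.items():
            cond_weights[list(config.conditions).index(label)] = np.asarray(cw)
    population = np.empty(n_cells, dtype=int)
    for ci in range(len(config.conditions)):
        mask = condition == ci
        population[mask] = rng.choice(
            config.n_populations, size=int(mask.sum()), p=cond_weights[ci])
    batch = rng.integers(config.n_batches, size=n_cells)
    depth = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))

    # low-quality cells: half thinned, half mitochondria-inflated
    n_lq = int(round(config.frac_low_quality * n_cells))
    lq_cells = rng.choice(n_cells, size=n_lq, replace=False)
    thin_cells = lq_cells[: n_lq // 2]
    mito_cells = lq_cells[n_lq // 2:]
    lq_kind = np.full(n_cells, "", dtype=object)
    lq_kind[thin_cells] = "thinned"
    lq_kind[mito_cells] = "mito" if config.n_mito_genes else "thinned"

    # per-population mean matrix on top of the baseline
    shift = np.exp(config.marker_log_shift)
    pop_factor = np.ones((config.n_populations, n_genes))
    for p, idx in marker_idx.items():
        pop_factor[p, idx] = shift
    for prog in programs:
        pop_factor[prog.sender, gene_pos[prog.ligand]] *= np.exp(prog.log_shift)
        pop_factor[prog.receiver, gene_pos[prog.receptor]] *= np.exp(prog.log_shift)

    # gene-wise batch offset (additive on the log scale, i.e. multiplicative
    # on the mean) applied to a random half of the genes for batches >= 1
    batch_genes = np.sort(rng.choice(n_genes, size=n_genes // 2, replace=False))
    batch_factor = np.ones((config.n_batches, n_genes))
    for b in range(1, config.n_batches):
        batch_factor[b, batch_genes] = np.exp(config.batch_log_offset * b)

    mu = base[None, :] * pop_factor[population] * batch_factor[batch] \
        * depth[:, None]
    if config.n_mito_genes and len(mito_cells):
        mu[np.ix_(mito_cells, mito_idx)] *= _MITO_INFLATION

    # NB counts via the gamma-Poisson mixture, size parameter nb_dispersion
    r = np.full(n_genes, config.nb_dispersion)
    r[mito_idx] = _MITO_NB_SIZE
    lam = rng.gamma(shape=r[None, :], scale=mu / r[None, :])
    counts = rng.poisson(lam)
    if len(thin_cells):
        counts[thin_cells] = rng.binomial(counts[thin_cells], _THINNING_KEEP)

    counts_df = pd.DataFrame(counts, index=cell_ids, columns=gene_ids)
    counts_df.index.name = "cell_id"
    cond_labels = np.asarray(config.conditions, dtype=object)[condition]
    meta = pd.DataFrame(
        {"condition": cond_labels, "batch": [f"batch{b}" for b in batch]},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth = GroundTruth(
        population=pd.Series(population, index=meta.index, name="population"),
        condition=meta["condition"].copy(),
        batch=meta["batch"].copy(),
        low_quality=pd.Series(lq_kind, index=meta.index, name="low_quality"),
        marker_genes=marker_genes,
        mito_genes=gene_ids[: config.n_mito_genes],
        batch_affected_genes=[gene_ids[i] for i in batch_genes],
        lr_pairs=pd.DataFrame(
            [dataclasses.asdict(p) for p in programs],
            columns=["ligand", "receptor", "sender", "receiver", "log_shift"],
        ),
    )
    return counts_df, meta, truth


def write_fixture(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    truth: GroundTruth | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a fixture to ``outdir`` in Matrix-Market + TSV form.

    Files: ``matrix.mtx`` (cells x genes, 1-based coordinate triplets),
    ``cells.tsv``, ``genes.tsv``, ``metadata.tsv`` and, when truth is given,
    ``truth_cells.tsv``, ``truth_genes.tsv``, ``truth_lr.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["matrix"] = outdir / "matrix.mtx"
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(counts.to_numpy()),
                     field="integer")
    paths["cells"] = outdir / "cells.tsv"
    pd.Series(counts.index).to_csv(paths["cells"], sep="\t", index=False,
                                   header=["cell_id"])
    paths["genes"] = outdir / "genes.tsv"
    pd.Series(counts.columns).to_csv(paths["genes"], sep="\t", index=False,
                                     header=["gene_id"])
    paths["metadata"] = outdir / "metadata.tsv"
    meta.to_csv(paths["metadata"], sep="\t")

    if truth is not None:
        cells = pd.DataFrame({
            "population": truth.population,
            "condition": truth.condition,
            "batch": truth.batch,
            "low_quality": truth.low_quality,
        })
        paths["truth_cells"] = outdir / "truth_cells.tsv"
        cells.to_csv(paths["truth_cells"], sep="\t")
        genes = pd.DataFrame(index=pd.Index(counts.columns, name="gene_id"))
        marker_of = truth.marker_of()
        genes["marker_of"] = marker_of.reindex(genes.index).fillna(-1).astype(int)
        genes["mito"] = genes.index.isin(truth.mito_genes).astype(int)
        genes["batch_affected"] = genes.index.isin(
            truth.batch_affected_genes).astype(int)
        paths["truth_genes"] = outdir / "truth_genes.tsv"
        genes.to_csv(paths["truth_genes"], sep="\t")
        paths["truth_lr"] = outdir / "truth_lr.tsv"
        truth.lr_pairs.to_csv(paths["truth_lr"], sep="\t", index=False)
    return paths


def read_fixture(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back a fixture written by :func:`write_fixture`."""
    from .io import read_counts

    outdir = Path(outdir)
    counts, _ = read_counts(outdir / "matrix.mtx", format="mtx",
                            cells_path=outdir / "cells.tsv",
                            genes_path=outdir / "genes.tsv")
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t", index_col="cell_id")
    return counts, meta


def make_lr_database(
    truth: GroundTruth,
    gene_ids: Sequence[str],
    n_decoys: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Ligand-receptor pair table: planted pairs plus random decoy pairs."""
    rng = np.random.default_rng(seed)
    rows = [(r.ligand, r.receptor, "planted")
            for r in truth.lr_pairs.itertuples()]
    used = {g for row in rows for g in row[:2]}
    free = [g for g in gene_ids
            if g not in used and g not in truth.mito_genes]
    pick = rng.choice(len(free), size=min(2 * n_decoys, len(free)),
                      replace=False)
    for i in range(len(pick) // 2):
        rows.append((free[pick[2 * i]], free[pick[2 * i + 1]], "decoy"))
    return pd.DataFrame(rows, columns=["ligand", "receptor", "annotation"])
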