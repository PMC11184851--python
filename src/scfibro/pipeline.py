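"""End-to-end orchestration: simulate/read -> QC -> reduce -> cluster ->
markers -> crosstalk, with a run manifest and reproducible seeding.

A :class:`PipelineConfig` is a flat record of every stage's parameters; the
defaults are the standing analysis parameters (QC 200/3000/10/50%, scale
1e4, 20 bins with the 0.0125/0.3 mean window and z-cutoff 0.5, 20 PCs,
perplexity 30, DBSCAN eps 0.5 then 1.0 with size floors 10 and 20, DEG
thresholds 0.5/0.01 and 0.25/0.05, post-hoc 1.0/0.01/10, top 10 markers,
1000 permutations). One global seed deterministically derives per-stage
seeds so a full run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import crosstalk as _crosstalk
from . import markers as _markers
from . import preprocess as _pre
from . import reduce as _reduce
from . import simulate as _sim
from .io import load_lr_database, read_counts

__all__ = ["PipelineConfig", "validate_config", "RunManifest",
           "PipelineResult", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("input", "qc", "reduce", "cluster", "markers", "crosstalk")


@dataclass
class PipelineConfig:
    """Flat configuration of the whole run. Unknown keys are rejected."""

    # input: either a counts file or simulation
    counts_path: str | None = None
    counts_format: str = "mtx"
    metadata_path: str | None = None
    lr_database_path: str | None = None
    out_dir: str | None = None
    # simulation (used when counts_path is None)
    n_cells: int = 3000
    n_genes: int = 2000
    n_populations: int = 12
    markers_per_population: int = 50
    marker_log_shift: float = 2.0
    nb_dispersion: float = 0.5
    frac_low_quality: float = 0.05
    n_batches: int = 2
    # qc
    min_genes: int = 200
    max_genes: int = 3000
    min_cells_per_gene: int = 10
    max_mito: float = 0.5
    scale_factor: float = 1e4
    # reduce
    n_bins: int = 20
    mean_low: float = 0.0125
    mean_high: float = 0.3
    z_cutoff: float = 0.5
    n_pcs: int = 20
    use_jackstraw: bool = False
    jackstraw_reps: int = 200
    jackstraw_test_pcs: int = 30
    perplexity: float = 30.0
    # cluster
    eps1: float = 0.5
    min_size1: int = 10
    eps2: float = 1.0
    min_size2: int = 20
    min_pts: int = 10
    # markers
    lfc1: float = 0.5
    fdr1: float = 0.01
    lfc2: float = 0.25
    p2: float = 0.05
    posthoc_lfc: float = 1.0
    posthoc_fdr: float = 0.01
    posthoc_min_degs: int = 10
    top_n: int = 10
    # crosstalk
    n_perm: int = 1000
    min_frac: float = 0.1
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if not 0 <= self.max_mito <= 1:
            raise ValueError("max_mito must lie in [0, 1]")
        if not 0 <= self.min_frac <= 1:
            raise ValueError("min_frac must lie in [0, 1]")
        if self.mean_low > self.mean_high:
            raise ValueError("mean_low must be <= mean_high")
        for name in ("n_cells", "n_genes", "n_populations", "n_bins",
                     "n_pcs", "min_size1", "min_size2", "min_pts", "n_perm",
                     "top_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("eps1", "eps2", "perplexity", "scale_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived deterministically from the global seed."""
        state = np.random.SeedSequence(self.seed).generate_state(5)
        names = ("simulate", "jackstraw", "tsne", "crosstalk", "lr_db")
        return {n: int(s % (2**31 - 1)) for n, s in zip(names, state)}


def validate_config(path: str | Path | None = None,
                    overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Parse a flat key-value config file (YAML mapping) into a
    :class:`PipelineConfig`. Missing keys take the defaults; unknown keys and
    out-of-range values are rejected with the offending field named."""
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        data.update(loaded)
    data.update(overrides or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _checksum(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
    h.update("|".join(map(str, df.index)).encode())
    h.update("|".join(map(str, df.columns)).encode())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage accounting: parameters, counts in/out and checksums."""

    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, **info: Any) -> None:
        self.stages[stage] = info

    def counts_chain_consistent(self) -> bool:
        order = [s for s in ALL_STAGES if s in self.stages]
        for prev, nxt in zip(order, order[1:]):
            a = self.stages[prev].get("n_cells_out")
            b = self.stages[nxt].get("n_cells_in")
            if a is not None and b is not None and a != b:
                return False
        return True


@dataclass
class PipelineResult:
    manifest: RunManifest
    counts: pd.DataFrame
    meta: pd.DataFrame
    truth: "_sim.GroundTruth | None"
    qc_report: "_pre.QcReport | None" = None
    normalized: pd.DataFrame | None = None
    corrected: pd.DataFrame | None = None
    hvg: "_reduce.HvgResult | None" = None
    pca: "_reduce.PcaResult | None" = None
    significant_pcs: list[int] | None = None
    embedding: "_reduce.Embedding | None" = None
    assignment: "_cluster.ClusterAssignment | None" = None
    composition: "_cluster.CompositionTable | None" = None
    markers: "_markers.MarkerCaller | None" = None
    top_markers: pd.DataFrame | None = None
    interactions: pd.DataFrame | None = None


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = ALL_STAGES) -> PipelineResult:
    """Execute the pipeline stages in order; any failure aborts with the
    stage named. Returns a :class:`PipelineResult` whose manifest reconciles
    cell counts at every stage boundary."""
    manifest = RunManifest()
    seeds = config.stage_seeds()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        if name not in ALL_STAGES:
            raise ValueError(f"unknown stage {name!r}")
        return name in stages

    def fail(name: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # ---- input -------------------------------------------------------
    truth = None
    try:
        if config.counts_path:
            counts, meta_skel = read_counts(config.counts_path,
                                            format=config.counts_format)
            if config.metadata_path:
                meta = pd.read_csv(config.metadata_path, sep="\t",
                                   index_col=0)
                meta.index = meta.index.astype(str)
                meta = meta.loc[counts.index]
            else:
                meta = pd.DataFrame(index=counts.index)
                meta["condition"] = "all"
                meta["batch"] = "batch0"
        else:
            gen = _sim.GeneratorConfig(
                n_cells=config.n_cells, n_genes=config.n_genes,
                n_populations=config.n_populations,
                markers_per_population=config.markers_per_population,
                marker_log_shift=config.marker_log_shift,
                nb_dispersion=config.nb_dispersion,
                frac_low_quality=config.frac_low_quality,
                n_batches=config.n_batches,
                lr_programs=[_sim.LrProgram()],
                seed=seeds["simulate"])
            counts, meta, truth = _sim.generate_counts(gen)
    except Exception as exc:  # noqa: BLE001
        fail("input", exc)
    manifest.record("input", params={"source": config.counts_path or "simulate"},
                    n_cells_out=counts.shape[0], n_genes_out=counts.shape[1],
                    checksum=_checksum(counts))
    result = PipelineResult(manifest=manifest, counts=counts, meta=meta,
                            truth=truth)
    if not stage("qc"):
        return result

    # ---- qc ----------------------------------------------------------
    try:
        qc = _pre.QCFilter(min_genes=config.min_genes,
                           max_genes=config.max_genes,
                           min_cells_per_gene=config.min_cells_per_gene,
                           max_mito=config.max_mito).fit(counts)
        filtered = qc.transform(counts)
        cell_meta = qc.cell_metadata_.loc[filtered.index]
        meta_f = meta.loc[filtered.index].join(cell_meta)
        norm = _pre.normalize_log(filtered, config.scale_factor)
        reg = _pre.regress_out_umi(norm, cell_meta["total_umi"])
        if meta_f["batch"].nunique() > 1:
            corrected = _pre.correct_batch(reg, meta_f["batch"])
        else:
            corrected = reg
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)
    manifest.record("qc", params={k: getattr(config, k) for k in
                                  ("min_genes", "max_genes",
                                   "min_cells_per_gene", "max_mito",
                                   "scale_factor")},
                    n_cells_in=counts.shape[0], n_cells_out=filtered.shape[0],
                    n_genes_in=counts.shape[1], n_genes_out=filtered.shape[1],
                    checksum=_checksum(norm))
    result.qc_report = qc.report_
    result.meta = meta_f
    result.normalized = norm
    result.corrected = corrected
    if out_dir:
        qc.report_.to_frame().to_csv(out_dir / "qc_report.tsv", sep="\t")
    if not stage("reduce"):
        return result

    # ---- reduce ------------------------------------------------------
    try:
        hvg = _reduce.select_hvg(norm, n_bins=config.n_bins,
                                 mean_low=config.mean_low,
                                 mean_high=config.mean_high,
                                 z_cutoff=config.z_cutoff)
        if not hvg.selected:
            raise ValueError("no highly variable genes selected")
        n_comp = min(config.n_pcs, len(hvg.selected) - 1,
                     corrected.shape[0] - 1)
        if config.use_jackstraw:
            n_comp = min(config.jackstraw_test_pcs, len(hvg.selected) - 1,
                         corrected.shape[0] - 1)
        pca = _reduce.run_pca(corrected, hvg.selected, n_components=n_comp)
        sig = None
        n_use = min(config.n_pcs, n_comp)
        if config.use_jackstraw:
            sig = _reduce.jackstraw_significant_pcs(
                corrected, hvg.selected, n_test_pcs=n_comp,
                n_reps=config.jackstraw_reps, seed=seeds["jackstraw"])
            if sig:
                n_use = min(max(sig), n_comp)
        emb = _reduce.run_tsne(pca, n_pcs=n_use,
                               perplexity=config.perplexity,
                               seed=seeds["tsne"])
    except Exception as exc:  # noqa: BLE001
        fail("reduce", exc)
    manifest.record("reduce", params={k: getattr(config, k) for k in
                                      ("n_bins", "mean_low", "mean_high",
                                       "z_cutoff", "n_pcs", "use_jackstraw",
                                       "perplexity")} | {"n_hvg":
                                                         len(hvg.selected),
                                                         "n_pcs_used": n_use},
                    n_cells_in=norm.shape[0], n_cells_out=emb.coords.shape[0],
                    checksum=_checksum(emb.coords))
    result.hvg = hvg
    result.pca = pca
    result.significant_pcs = sig
    result.embedding = emb
    if out_dir:
        hvg.stats.to_csv(out_dir / "hvg.tsv", sep="\t")
        emb.coords.to_csv(out_dir / "embedding.tsv", sep="\t")
    if not stage("cluster"):
        return result

    # ---- cluster -----------------------------------------------------
    try:
        assign = _cluster.dbscan_two_pass(
            emb, eps1=config.eps1, min_size1=config.min_size1,
            eps2=config.eps2, min_size2=config.min_size2,
            min_pts=config.min_pts)
        composition = _cluster.composition_by_group(assign, meta_f)
    except Exception as exc:  # noqa: BLE001
        fail("cluster", exc)
    manifest.record("cluster", params={k: getattr(config, k) for k in
                                       ("eps1", "min_size1", "eps2",
                                        "min_size2", "min_pts")},
                    n_cells_in=emb.coords.shape[0],
                    n_cells_out=int(len(assign.retained)),
                    n_removed=assign.n_removed,
                    removed_percent=assign.removed_percent(),
                    n_clusters=assign.n_clusters,
                    checksum=_checksum(assign.table[["pass1", "final"]]))
    result.assignment = assign
    result.composition = composition
    if out_dir:
        assign.table.to_csv(out_dir / "clusters.tsv", sep="\t")
        composition.tests.to_csv(out_dir / "composition.tsv", sep="\t",
                                 index=False)
    if not stage("markers"):
        return result

    # ---- markers -----------------------------------------------------
    try:
        caller = _markers.MarkerCaller(
            min_log_diff1=config.lfc1, max_fdr1=config.fdr1,
            min_log_diff2=config.lfc2, max_p2=config.p2,
            posthoc_log_diff=config.posthoc_lfc,
            posthoc_fdr=config.posthoc_fdr,
            posthoc_min_degs=config.posthoc_min_degs,
        ).fit(norm.loc[assign.retained], assign)
        top = None
        if not caller.markers_.empty and caller.markers_["is_marker"].any():
            top, _ = _markers.top_markers(caller.markers_, n=config.top_n,
                                          expr=norm.loc[assign.retained],
                                          assign=assign)
    except Exception as exc:  # noqa: BLE001
        fail("markers", exc)
    manifest.record("markers", params={k: getattr(config, k) for k in
                                       ("lfc1", "fdr1", "lfc2", "p2",
                                        "posthoc_lfc", "posthoc_fdr",
                                        "posthoc_min_degs", "top_n")},
                    n_cells_in=int(len(assign.retained)),
                    n_cells_out=int(len(assign.retained)),
                    n_markers=int(caller.markers_["is_marker"].sum()),
                    min_pair_degs=(int(caller.validity_["n_degs"].min())
                                   if len(caller.validity_) else None))
    result.markers = caller
    result.top_markers = top
    if out_dir:
        caller.markers_.to_csv(out_dir / "markers.tsv", sep="\t", index=False)
        caller.validity_.to_csv(out_dir / "cluster_validity.tsv", sep="\t",
                                index=False)
        if top is not None:
            top.to_csv(out_dir / "top_markers.tsv", sep="\t", index=False)
    if not stage("crosstalk"):
        return result

    # ---- crosstalk ---------------------------------------------------
    try:
        if config.lr_database_path:
            db = load_lr_database(config.lr_database_path)
        elif truth is not None:
            db = _sim.make_lr_database(truth, counts.columns,
                                       seed=seeds["lr_db"])
        else:
            raise ValueError("no ligand-receptor database: set "
                             "lr_database_path")
        interactions = _crosstalk.permutation_pvalues(
            norm.loc[assign.retained], assign, db, n_perm=config.n_perm,
            min_frac=config.min_frac, seed=seeds["crosstalk"])
    except Exception as exc:  # noqa: BLE001
        fail("crosstalk", exc)
    manifest.record("crosstalk", params={"n_perm": config.n_perm,
                                         "min_frac": config.min_frac,
                                         "n_pairs": len(db)},
                    n_cells_in=int(len(assign.retained)),
                    n_cells_out=int(len(assign.retained)),
                    n_tested=int((~interactions["excluded"]).sum()))
    result.interactions = interactions
    if out_dir:
        interactions.to_csv(out_dir / "interactions.tsv", sep="\t",
                            index=False)
        _crosstalk.export_dotplot_table(interactions).to_csv(
            out_dir / "interactions_dotplot.tsv", sep="\t", index=False)
    return result
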