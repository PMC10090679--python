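"""End-to-end pipeline: QC -> embed/cluster -> stratify -> trajectory ->
modules -> abundance, with every stage output written as a diffable CSV.

All randomness flows from ``config.seed`` through per-stage derived seeds
(logged), so identical (config, counts) inputs give byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import cellcycle as cc
from . import embedding as em
from . import modules as gm
from . import qc as qcmod
from . import strata as st
from .config import PipelineConfig
from .io import CountMatrix, NormalizedMatrix

log = logging.getLogger("esostrata")

FLOAT_FMT = "%.6g"  # 6 significant digits in every written table


@dataclass
class PipelineResult:
    counts: CountMatrix
    qc_report: qcmod.QCReport
    norm: NormalizedMatrix
    pca: np.ndarray
    umap: np.ndarray
    clusters: em.ClusterAssignment
    strata: pd.DataFrame
    dotplot: pd.DataFrame
    top_markers: dict
    phases: pd.DataFrame
    trajectory: cc.TrajectoryGraph
    fate_report: pd.DataFrame
    modules: gm.GeneModuleSet
    module_scores: pd.DataFrame
    proportions: pd.DataFrame
    calls: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage where it happened."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with context
                raise StageError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix,
    out_dir: str | Path | None = None,
    root_override: int | None = None,
) -> PipelineResult:
    """Run every stage on ``counts`` and optionally write the CSV bundle."""
    seed_of = {s: config.stage_seed(s) for s in
               ("qc", "cluster", "trajectory", "modules")}
    for s, sd in seed_of.items():
        log.info("stage %s: derived seed %d", s, sd)

    qc_counts, qc_report = _stage("qc")(qcmod.run_qc)(
        counts,
        min_cells_per_gene=config.min_cells_per_gene,
        gene_bounds=config.gene_count_bounds,
        total_bounds=config.total_count_bounds,
        per_condition_cap=config.per_condition_cap,
        seed=seed_of["qc"],
        cap_to_min=config.cap_to_min,
    )

    norm = _stage("normalize")(em.normalize_log10)(qc_counts)
    if "replicate" in qc_counts.cell_meta.columns:
        reg = _stage("regress")(em.regress_covariate)(
            norm, qc_counts.cell_meta["replicate"].to_numpy()
        )
    else:
        reg = norm
    pca = _stage("pca")(em.run_pca)(reg, config.n_pcs, seed=seed_of["cluster"])
    umap_xy = _stage("umap")(em.run_umap)(
        pca,
        out_dims=config.umap_dims,
        seed=seed_of["cluster"],
        n_neighbors=config.umap_n_neighbors,
        min_dist=config.umap_min_dist,
    )
    space = umap_xy if config.cluster_space == "umap" else pca
    clusters = _stage("cluster")(em.cluster_cells)(
        space, resolution=config.cluster_resolution, seed=seed_of["cluster"],
        k=config.knn_k,
    )

    x_means = _stage("stratify")(st.cluster_marker_mean)(norm, clusters.labels, config.x_marker)
    y_means = st.cluster_marker_mean(norm, clusters.labels, config.y_marker)
    params = st.StripParams(
        half_width=config.strip_half_width,
        x_marker=config.x_marker,
        y_marker=config.y_marker,
    )
    strata = _stage("stratify")(st.classify_strata)(x_means, y_means, params)
    dotplot = st.dotplot_stats(norm, clusters.labels)
    markers = st.top_markers_per_cluster(norm, clusters.labels)

    phases = _stage("trajectory")(cc.phase_scores)(
        norm,
        n_bins=config.n_expression_bins,
        n_ctrl=config.n_control_genes,
        seed=seed_of["trajectory"],
    )
    # root selection reads cluster adjacency off the expression-space (PCA)
    # neighbor graph: 2-D layout distances are not faithful to it
    knn_adj = em.knn_graph(pca, k=config.knn_k)
    root = _stage("trajectory")(cc.select_root)(
        clusters.labels, strata, phases, knn_adj, override=root_override
    )
    traj = _stage("trajectory")(cc.build_tree_and_pseudotime)(
        umap_xy, clusters.labels, root, cell_ids=qc_counts.cell_ids
    )
    fate = cc.terminal_fate_report(traj, qc_counts.cell_meta)

    modules = _stage("modules")(gm.find_gene_modules)(
        norm,
        min_module_size=config.min_module_size,
        resolution=config.module_resolution,
        seed=seed_of["modules"],
    )
    module_scores = gm.score_modules(modules, norm, clusters.labels)

    props = _stage("abundance")(ab.cluster_proportions)(
        clusters.labels, qc_counts.cell_meta
    )
    calls = {}
    for case in ("EoE", "ESCC"):
        if case in set(qc_counts.cell_meta["condition"]):
            calls[case] = _stage("abundance")(ab.compare_abundance)(
                props, (case, "control"), alpha=config.alpha,
                adjust=config.adjust_method,
            )
    summary = ab.enrichment_summary(calls, strata) if calls else None

    result = PipelineResult(
        counts=qc_counts, qc_report=qc_report, norm=norm, pca=pca, umap=umap_xy,
        clusters=clusters, strata=strata, dotplot=dotplot, top_markers=markers,
        phases=phases, trajectory=traj, fate_report=fate, modules=modules,
        module_scores=module_scores, proportions=props, calls=calls,
        summary=summary,
    )
    if out_dir is not None:
        write_result(result, out_dir)
    return result


def write_result(res: PipelineResult, out_dir: str | Path) -> None:
    """Write every stage table as UTF-8 CSV with 6-significant-digit floats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx = pd.Index(res.counts.cell_ids, name="cell_id")

    res.qc_report.to_frame().to_csv(out / "qc_report.csv", index=False)
    pd.DataFrame(res.pca, index=idx).to_csv(out / "pca_scores.csv", float_format=FLOAT_FMT)
    pd.DataFrame(res.umap, index=idx, columns=["umap1", "umap2"]).to_csv(
        out / "umap.csv", float_format=FLOAT_FMT
    )
    pd.DataFrame({"cluster": res.clusters.labels}, index=idx).to_csv(out / "clusters.csv")
    res.strata.to_csv(out / "strata.csv", float_format=FLOAT_FMT)
    res.dotplot.to_csv(out / "dotplot_stats.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(
        [(c, r + 1, g) for c, gs in res.top_markers.items() for r, g in enumerate(gs)],
        columns=["cluster", "rank", "gene"],
    ).to_csv(out / "top_markers.csv", index=False)
    res.phases.to_csv(out / "phase_scores.csv", float_format=FLOAT_FMT)
    res.trajectory.pseudotime.to_frame().to_csv(out / "pseudotime.csv", float_format=FLOAT_FMT)
    pd.DataFrame(res.trajectory.edges, columns=["from", "to", "length"]).to_csv(
        out / "tree_edges.csv", index=False, float_format=FLOAT_FMT
    )
    res.fate_report.to_csv(out / "fate_report.csv", index=False, float_format=FLOAT_FMT)
    res.modules.membership().rename_axis("gene_id").to_frame().to_csv(out / "module_membership.csv")
    res.module_scores.to_csv(out / "module_scores.csv", float_format=FLOAT_FMT)
    res.proportions.to_csv(out / "proportions.csv", float_format=FLOAT_FMT)
    if res.calls:
        pd.concat(res.calls.values()).to_csv(out / "abundance_calls.csv", float_format=FLOAT_FMT)
    if res.summary is not None:
        res.summary.to_csv(out / "enrichment_summary.csv", float_format=FLOAT_FMT)
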