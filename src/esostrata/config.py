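"""Pipeline configuration.

All tunable thresholds of the pipeline live in a single :class:`PipelineConfig`
object that can be round-tripped through YAML.  The defaults are the published
settings of the murine esophageal-epithelium study this pipeline reimplements:
gene filter at 4 expressing cells, cell filters at 250–3,500 unique genes and
100–9,500 total UMI, equalized downsampling to 1,500 cells per condition,
50 principal components, 2-D UMAP, Leiden resolution 3e-3, and the slope-1
Krt5/Krtdap strip of half-width 0.3.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

VALID_ADJUST = ("BH", "bonferroni")


@dataclass
class PipelineConfig:
    seed: int = 0
    # QC
    min_cells_per_gene: int = 4
    gene_count_bounds: tuple[int, int] = (250, 3500)
    total_count_bounds: tuple[int, int] = (100, 9500)
    per_condition_cap: int = 1500
    cap_to_min: bool = False
    # embedding / clustering
    n_pcs: int = 50
    umap_dims: int = 2
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    knn_k: int = 20
    cluster_resolution: float = 3e-3
    cluster_space: str = "umap"  # or "pca"
    # stratum classifier
    x_marker: str = "Krt5"
    y_marker: str = "Krtdap"
    strip_half_width: float = 0.3
    # cell cycle scoring
    n_expression_bins: int = 25
    n_control_genes: int = 50
    # gene modules
    min_module_size: int = 10
    module_resolution: float = 0.5
    # abundance testing
    adjust_method: str = "BH"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.gene_count_bounds = tuple(self.gene_count_bounds)
        self.total_count_bounds = tuple(self.total_count_bounds)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.gene_count_bounds
        if lo > hi:
            raise ValueError(f"gene_count_bounds out of order: {lo} > {hi}")
        lo, hi = self.total_count_bounds
        if lo > hi:
            raise ValueError(f"total_count_bounds out of order: {lo} > {hi}")
        if self.per_condition_cap < 1:
            raise ValueError("per_condition_cap must be >= 1")
        if self.cluster_resolution <= 0:
            raise ValueError("cluster_resolution must be > 0")
        if self.strip_half_width < 0:
            raise ValueError("strip_half_width must be >= 0")
        if self.adjust_method not in VALID_ADJUST:
            raise ValueError(f"adjust_method must be one of {VALID_ADJUST}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")

    # -- seed bookkeeping -------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed (< 2**31) from the global seed.

        Stages draw independent streams so that re-running one stage with the
        same global seed reproduces it regardless of the other stages.
        """
        ss = np.random.SeedSequence(self.seed, spawn_key=(_stage_key(stage),))
        return int(ss.generate_state(1)[0] % (2**31))

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["gene_count_bounds"] = list(self.gene_count_bounds)
        d["total_count_bounds"] = list(self.total_count_bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


_STAGE_KEYS = {
    "synth": 1,
    "qc": 2,
    "cluster": 3,
    "stratify": 4,
    "trajectory": 5,
    "modules": 6,
    "abundance": 7,
    "tumor": 8,
}


def _stage_key(stage: str) -> int:
    try:
        return _STAGE_KEYS[stage]
    except KeyError:
        raise KeyError(
            f"unknown pipeline stage {stage!r}; known stages: {sorted(_STAGE_KEYS)}"
        ) from None
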