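"""Basal / suprabasal / superficial classification of clusters.

Each cluster is placed by its mean normalized log10 expression of a basal
marker (x, default Krt5) and a differentiation marker (y, default Krtdap).
Clusters within vertical distance ``half_width`` (default 0.3) of the slope-1
line through the origin — the strip bounded by the lines through (0, -0.3)
and (0, 0.3) — are suprabasal: neither marker sufficiently dominates.  Below
the strip (Krt5 dominant) is basal; above it (Krtdap dominant) is superficial.
Boundary points belong to the strip.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

__all__ = [
    "StripParams",
    "cluster_marker_mean",
    "classify_strata",
    "dotplot_stats",
    "top_markers_per_cluster",
    "DEFAULT_MARKER_PANEL",
]

# conventional esophageal basal / differentiated markers for dot-plot summaries
DEFAULT_MARKER_PANEL = ("Krt5", "Trp63", "Krt14", "Krtdap", "Krt13", "Krt4")


@dataclass
class StripParams:
    slope: float = 1.0
    half_width: float = 0.3
    x_marker: str = "Krt5"
    y_marker: str = "Krtdap"

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")


def cluster_marker_mean(
    norm: NormalizedMatrix, clusters: np.ndarray, gene: str
) -> dict[int, float]:
    """Arithmetic mean of a gene's normalized values per cluster."""
    gi = norm.gene_index(gene)
    col = norm.values[:, gi]
    clusters = np.asarray(clusters)
    return {
        int(c): float(col[clusters == c].mean()) for c in np.unique(clusters)
    }


def classify_strata(
    x_means: dict[int, float],
    y_means: dict[int, float],
    params: StripParams | None = None,
) -> pd.DataFrame:
    """Stratum call per cluster from its (x̄, ȳ) marker means.

    With d = ȳ − slope·x̄: |d| ≤ half_width → suprabasal; d < −half_width →
    basal; d > half_width → superficial.
    """
    params = params or StripParams()
    rows = []
    for c in sorted(x_means):
        x, y = x_means[c], y_means[c]
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError(f"non-finite marker mean for cluster {c}")
        d = y - params.slope * x
        if abs(d) <= params.half_width:
            stratum = "suprabasal"
        elif d < 0:
            stratum = "basal"
        else:
            stratum = "superficial"
        rows.append({"cluster": c, "x_mean": x, "y_mean": y, "stratum": stratum})
    return pd.DataFrame(rows).set_index("cluster")


def dotplot_stats(
    norm: NormalizedMatrix, clusters: np.ndarray, panel=DEFAULT_MARKER_PANEL
) -> pd.DataFrame:
    """Dot-plot summary: per (gene, cluster) the z-score of the cluster-average
    expression across clusters and the fraction of cells with nonzero
    expression.  Missing panel genes are reported and skipped; with a single
    cluster z-scores are emitted as 0 with a warning.
    """
    import warnings

    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    rows = []
    for gene in panel:
        try:
            gi = norm.gene_index(gene)
        except KeyError:
            warnings.warn(f"panel gene {gene!r} not in matrix; skipped")
            continue
        col = norm.values[:, gi]
        means = np.array([col[clusters == c].mean() for c in uniq])
        fracs = np.array([(col[clusters == c] > 0).mean() for c in uniq])
        sd = means.std()
        if len(uniq) < 2 or sd == 0:
            if len(uniq) < 2:
                warnings.warn("single cluster: z-scores undefined, emitted as 0")
            z = np.zeros_like(means)
        else:
            z = (means - means.mean()) / sd
        for c, zz, ff, mm in zip(uniq, z, fracs, means):
            rows.append(
                {"cluster": int(c), "gene": gene, "zscore": float(zz),
                 "frac_nonzero": float(ff), "mean_expr": float(mm)}
            )
    return pd.DataFrame(rows)


def top_markers_per_cluster(
    norm: NormalizedMatrix, clusters: np.ndarray, k: int = 5
) -> dict[int, list[str]]:
    """Up to ``k`` most uniquely up-regulated genes per cluster.

    Genes are ranked by cluster mean minus the best mean among all other
    clusters; ties break alphabetically.
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if len(uniq) < 2:
        raise ValueError("top markers need at least two clusters")
    means = np.vstack([norm.values[clusters == c].mean(axis=0) for c in uniq])
    result: dict[int, list[str]] = {}
    genes = norm.gene_ids.astype(str)
    for i, c in enumerate(uniq):
        others = np.delete(means, i, axis=0).max(axis=0)
        specificity = means[i] - others
        order = np.lexsort((genes, -specificity))
        result[int(c)] = [str(genes[j]) for j in order[:k]]
    return result
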