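"""Normalization, covariate regression, PCA, UMAP and Leiden clustering.

Normalization is median-total size-factor scaling followed by log10(1 + x),
so zeros stay zero and the values sit on the "normalized log10 expression"
scale used by the marker-strip classifier.  Clustering follows the Monocle3
convention: a kNN graph built in 2-D UMAP space (k = 20) partitioned by
Leiden under the CPM objective at resolution 3e-3; PCA-space clustering is
available behind a switch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, NormalizedMatrix

__all__ = [
    "normalize_log10",
    "regress_covariate",
    "run_pca",
    "run_umap",
    "knn_graph",
    "cluster_cells",
    "ClusterAssignment",
]


def normalize_log10(cm: CountMatrix) -> NormalizedMatrix:
    """log10(1 + count * median_total / cell_total); all-zero cells stay zero."""
    totals = np.asarray(cm.counts.sum(axis=1), dtype=float).ravel()
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} cells have zero total counts; rows left zero"
        )
    median_total = np.median(totals[nonzero]) if nonzero.any() else 1.0
    scale = np.zeros_like(totals)
    scale[nonzero] = median_total / totals[nonzero]
    dense = cm.counts.toarray().astype(float)
    values = np.log10(1.0 + dense * scale[:, None])
    return NormalizedMatrix(values=values, cell_ids=cm.cell_ids, gene_ids=cm.gene_ids)


def regress_covariate(norm: NormalizedMatrix, covariate: np.ndarray) -> NormalizedMatrix:
    """Remove per-gene covariate-level means, re-centered to the global mean.

    Stands in for batch regression: within each covariate level the per-gene
    mean is subtracted and the global per-gene mean added back, equalizing
    level means exactly.  The result feeds PCA/UMAP/clustering only — marker
    means are always computed on the unregressed normalized matrix.
    """
    covariate = np.asarray(covariate)
    if len(covariate) != len(norm.cell_ids):
        raise ValueError("one covariate label required per cell")
    levels = np.unique(covariate)
    if len(levels) == 1:
        return NormalizedMatrix(norm.values.copy(), norm.cell_ids, norm.gene_ids)
    out = norm.values.copy()
    grand = out.mean(axis=0)
    for lv in levels:
        mask = covariate == lv
        out[mask] += grand - out[mask].mean(axis=0)
    return NormalizedMatrix(out, norm.cell_ids, norm.gene_ids)


def run_pca(norm: NormalizedMatrix, n_components: int = 50, seed: int = 0) -> np.ndarray:
    """PC scores of the gene-standardized matrix with a fixed sign convention.

    Genes are centered and scaled to unit variance (zero-variance genes left
    centered); each component's sign is set so its largest-magnitude loading
    is positive.
    """
    X = norm.values
    n_cells, n_genes = X.shape
    k = min(n_components, n_cells, n_genes)
    if k < n_components:
        warnings.warn(f"reducing n_components from {n_components} to {k}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(Z)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def run_umap(
    scores: np.ndarray,
    out_dims: int = 2,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2-D UMAP embedding, deterministic under a fixed seed."""
    import umap  # deferred: numba compilation is slow to import

    n = scores.shape[0]
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors clamped from {n_neighbors} to {max(2, n - 1)}")
        n_neighbors = max(2, n - 1)
    reducer = umap.UMAP(
        n_components=out_dims,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        return np.asarray(reducer.fit_transform(scores), dtype=float)


def knn_graph(points: np.ndarray, k: int = 20) -> sp.csr_matrix:
    """Symmetric unweighted kNN adjacency (no self loops)."""
    n = points.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    adj = nn.kneighbors_graph(points, mode="connectivity")
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj = adj.maximum(adj.T)  # mutual-or symmetrization
    return adj.tocsr()


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # contiguous ints from 0, sorted by descending size
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def cluster_cells(
    points: np.ndarray,
    resolution: float = 3e-3,
    seed: int = 0,
    k: int = 20,
) -> ClusterAssignment:
    """Leiden/CPM community detection on a kNN graph of ``points``.

    ``points`` is usually the UMAP embedding (the Monocle3 convention) but PCA
    scores work too.  Labels are relabeled in order of descending cluster
    size.
    """
    adj = knn_graph(points, k=k)
    sources, targets = adj.nonzero()
    mask = sources < targets
    g = ig.Graph(
        n=adj.shape[0], edges=list(zip(sources[mask].tolist(), targets[mask].tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.CPMVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel by descending size, ties by first appearance
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[x] for x in raw], dtype=int)
    return ClusterAssignment(labels=labels, resolution=resolution)
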