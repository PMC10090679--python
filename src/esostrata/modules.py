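"""Co-expression gene-module discovery, per-cluster module scores, and a
generic hypergeometric over-representation test.

Modules are found the way the pipeline finds cell clusters, but with the
matrix transposed: genes (standardized across cells so magnitude does not
dominate co-expression) are embedded by UMAP with cells as features and
partitioned by Leiden on a kNN graph.  Modules smaller than
``min_module_size`` are merged into the nearest larger module by centroid
distance in the embedding.  Module ids are ordered by size (module 1 is the
largest).
"""
from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .embedding import knn_graph
from .io import NormalizedMatrix

__all__ = ["find_gene_modules", "score_modules", "ora_enrichment", "GeneModuleSet"]


class GeneModuleSet(dict):
    """module id (int, 1-based) -> list of gene ids; disjoint by construction."""

    def membership(self) -> pd.Series:
        rows = {g: m for m, genes in self.items() for g in genes}
        return pd.Series(rows, name="module")


def find_gene_modules(
    norm: NormalizedMatrix,
    min_module_size: int = 10,
    resolution: float = 0.5,
    seed: int = 0,
    k: int = 15,
) -> GeneModuleSet:
    """Leiden communities of genes in a UMAP embedding of the gene space."""
    import umap

    X = norm.values
    sd = X.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size < min_module_size:
        raise ValueError("not enough genes with nonzero variance for module discovery")
    if keep.size < len(sd):
        warnings.warn(f"{len(sd) - keep.size} zero-variance genes excluded from modules")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    G = Z.T  # genes x cells

    n_neighbors = min(30, G.shape[0] - 1)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=0.1, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = np.asarray(reducer.fit_transform(G), dtype=float)

    adj = knn_graph(emb, k=min(k, G.shape[0] - 1))
    s, t = adj.nonzero()
    mask = s < t
    g = ig.Graph(n=adj.shape[0], edges=list(zip(s[mask].tolist(), t[mask].tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership)

    # merge undersized communities into the nearest large one by centroid
    ids, counts = np.unique(labels, return_counts=True)
    large = ids[counts >= min_module_size]
    if large.size == 0:
        large = ids[[np.argmax(counts)]]
    centroids = {i: emb[labels == i].mean(axis=0) for i in ids}
    for i in ids:
        if i not in large:
            nearest = min(large, key=lambda j: np.linalg.norm(centroids[i] - centroids[j]))
            labels[labels == i] = nearest

    # order by size, 1-based ids
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    gene_ids = norm.gene_ids[keep]
    out = GeneModuleSet()
    for new, old in enumerate(order, start=1):
        out[new] = [str(g) for g in gene_ids[labels == old]]
    return out


def score_modules(
    modules: GeneModuleSet, norm: NormalizedMatrix, clusters: np.ndarray
) -> pd.DataFrame:
    """Modules × clusters score matrix.

    Entry (m, c) is the mean over module-m genes of the cluster-c mean
    normalized expression, z-scaled across clusters within each module row.
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    cluster_means = np.vstack(
        [norm.values[clusters == c].mean(axis=0) for c in uniq]
    )  # clusters x genes
    rows = {}
    for m, genes in modules.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        vals = cluster_means[:, idx].mean(axis=1)
        sd = vals.std()
        rows[m] = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[int(c) for c in uniq]
    ).rename_axis(index="module", columns="cluster")


def ora_enrichment(
    module_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a module in gene sets.

    For a universe of N genes, a module of n genes, and a set with K universe
    genes of which x overlap the module, p = P(X >= x), X ~
    Hypergeom(N, K, n).  p-values are BH-adjusted across sets.  Sets disjoint
    from the universe are skipped with a warning.
    """
    universe_set = set(universe)
    module = set(module_genes)
    if not module <= universe_set:
        raise ValueError("universe must contain every module gene")
    N, n = len(universe_set), len(module)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe_set
        if not in_universe:
            warnings.warn(f"gene set {name!r} is disjoint from the universe; skipped")
            continue
        K = len(in_universe)
        x = len(in_universe & module)
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append({"gene_set": name, "set_size": K, "overlap": x, "p": p})
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p", kind="stable").reset_index(drop=True)
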