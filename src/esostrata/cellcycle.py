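"""Cell-cycle phase scoring, pseudotime root selection, and the principal tree.

Phase scoring is the standard module score: genes are binned by average
expression; each phase gene is paired with expression-matched control genes
drawn from its bin; the score is the mean expression of the phase set minus
the mean of the controls.  A cell is S or G2M by the larger positive score
(ties toward S), else G1/G0.

The trajectory backbone is a minimum spanning tree over cluster centroids in
UMAP space — a deterministic approximation of a learned principal graph,
sufficient for root/branch/leaf analysis.  The root is chosen by the study's
rule: among basal clusters whose modal phase is G1/G0, the one most connected
(kNN edges) to the most S-enriched basal cluster.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path

from .io import NormalizedMatrix
from .synthetic import default_cycle_genes

__all__ = [
    "phase_scores",
    "select_root",
    "build_tree_and_pseudotime",
    "terminal_fate_report",
    "TrajectoryGraph",
]

PHASES = ("G1/G0", "S", "G2M")


def _module_score(
    values: np.ndarray,
    gene_idx: np.ndarray,
    bins: np.ndarray,
    rng: np.random.Generator,
    n_ctrl: int,
) -> np.ndarray:
    """Mean over the gene set minus mean over expression-matched controls."""
    ctrl_idx = []
    for gi in gene_idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl_idx.append(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)
    return values[:, gene_idx].mean(axis=1) - values[:, ctrl_idx].mean(axis=1)


def call_phase(s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """Phase by the larger positive score; G1/G0 when both are non-positive.

    An exact positive tie goes to S (arbitrary convention, applied uniformly).
    """
    s_score = np.asarray(s_score)
    g2m_score = np.asarray(g2m_score)
    return np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1/G0",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )


def phase_scores(
    norm: NormalizedMatrix,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M module scores and the resulting phase call."""
    s_genes = s_genes if s_genes is not None else default_cycle_genes("S")
    g2m_genes = g2m_genes if g2m_genes is not None else default_cycle_genes("G2M")
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    s_idx = np.array([gene_pos[g] for g in s_genes if g in gene_pos], dtype=int)
    g2m_idx = np.array([gene_pos[g] for g in g2m_genes if g in gene_pos], dtype=int)
    missing_s = [g for g in s_genes if g not in gene_pos]
    missing_g = [g for g in g2m_genes if g not in gene_pos]
    if s_idx.size == 0 or g2m_idx.size == 0:
        raise ValueError(
            f"no phase genes present in matrix; missing S: {missing_s[:5]}..., "
            f"missing G2M: {missing_g[:5]}..."
        )
    avg = norm.values.mean(axis=0)
    # equal-frequency bins of average expression
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1
    )
    rng = np.random.default_rng(seed)
    s_score = _module_score(norm.values, s_idx, bins, rng, n_ctrl)
    g2m_score = _module_score(norm.values, g2m_idx, bins, rng, n_ctrl)
    phase = call_phase(s_score, g2m_score)
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=pd.Index(norm.cell_ids, name="cell_id"),
    )


def select_root(
    clusters: np.ndarray,
    strata: pd.DataFrame,
    phases: pd.DataFrame,
    knn_adj: sp.spmatrix,
    override: int | None = None,
) -> int:
    """Pick the pseudotime root cluster.

    Rule: among basal clusters with modal phase G1/G0, choose the one with
    most kNN edges to the most S-enriched basal cluster; ties break by higher
    G1/G0 fraction, then lowest cluster id.  ``override`` short-circuits the
    rule.
    """
    if override is not None:
        return int(override)
    clusters = np.asarray(clusters)
    phase = phases["phase"].to_numpy()
    basal = [int(c) for c in strata.index if strata.loc[c, "stratum"] == "basal"]
    if not basal:
        raise ValueError("no basal cluster found; pass an explicit root override")

    def frac(c: int, ph: str) -> float:
        mask = clusters == c
        return float((phase[mask] == ph).mean()) if mask.any() else 0.0

    candidates = [c for c in basal if pd.Series(phase[clusters == c]).mode().iloc[0] == "G1/G0"]
    if not candidates:
        raise ValueError(
            "no basal cluster with modal phase G1/G0; pass an explicit root override"
        )
    s_target = max(basal, key=lambda c: (frac(c, "S"), -c))
    adj = sp.csr_matrix(knn_adj)

    def edges_to_target(c: int) -> int:
        rows = np.flatnonzero(clusters == c)
        cols = np.flatnonzero(clusters == s_target)
        return int(adj[rows][:, cols].sum())

    return int(
        max(candidates, key=lambda c: (edges_to_target(c), frac(c, "G1/G0"), -c))
    )


@dataclass
class TrajectoryGraph:
    centroids: np.ndarray  # n_clusters x 2, UMAP space
    edges: list  # (u, v, length) MST edges
    root: int
    cluster_ids: np.ndarray
    pseudotime: pd.Series  # per cell
    cell_clusters: np.ndarray = field(repr=False, default=None)  # type: ignore

    def centroid_distance(self) -> dict[int, float]:
        """Tree geodesic distance from the root to each cluster centroid."""
        n = len(self.cluster_ids)
        pos = {c: i for i, c in enumerate(self.cluster_ids)}
        W = sp.lil_matrix((n, n))
        for u, v, w in self.edges:
            W[pos[u], pos[v]] = w
            W[pos[v], pos[u]] = w
        dist = shortest_path(W.tocsr(), indices=pos[self.root])
        return {int(c): float(dist[pos[c]]) for c in self.cluster_ids}

    def leaves(self) -> list[int]:
        deg: dict[int, int] = {int(c): 0 for c in self.cluster_ids}
        for u, v, _ in self.edges:
            deg[int(u)] += 1
            deg[int(v)] += 1
        return [c for c, d in deg.items() if d == 1 and c != self.root]

    def parents(self) -> dict[int, int]:
        """Parent of each cluster on the path to the root (root maps to itself)."""
        adj: dict[int, list[int]] = {int(c): [] for c in self.cluster_ids}
        for u, v, _ in self.edges:
            adj[int(u)].append(int(v))
            adj[int(v)].append(int(u))
        parent = {self.root: self.root}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in parent:
                    parent[nb] = node
                    stack.append(nb)
        return parent


def build_tree_and_pseudotime(
    embedding: np.ndarray,
    clusters: np.ndarray,
    root: int,
    cell_ids: np.ndarray | None = None,
) -> TrajectoryGraph:
    """MST over cluster centroids plus per-cell pseudotime.

    A cell's pseudotime is the tree geodesic from the root centroid to its
    cluster centroid plus its offset projected on the incident edge (for the
    root cluster, the edge toward its nearest child), clipped at zero and
    anchored so the root cluster's minimum is exactly 0.
    """
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if root not in uniq:
        raise ValueError(f"root cluster {root} not among cluster labels")
    centroids = np.vstack([embedding[clusters == c].mean(axis=0) for c in uniq])
    pos = {int(c): i for i, c in enumerate(uniq)}
    # complete distance graph -> MST
    diff = centroids[:, None, :] - centroids[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    mst = minimum_spanning_tree(sp.csr_matrix(D))
    edges = [
        (int(uniq[u]), int(uniq[v]), float(mst[u, v]))
        for u, v in zip(*mst.nonzero())
    ]
    graph = TrajectoryGraph(
        centroids=centroids,
        edges=edges,
        root=int(root),
        cluster_ids=uniq.astype(int),
        pseudotime=None,  # filled below
        cell_clusters=clusters,
    )
    geo = graph.centroid_distance()
    parent = graph.parents()

    # direction of each cluster's incident edge, pointing away from the root
    direction = np.zeros_like(centroids)
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        if c != p:
            children.setdefault(p, []).append(c)
    for c in uniq:
        c = int(c)
        if c == int(root):
            kids = children.get(c, [])
            if kids:
                nearest = min(kids, key=lambda k: geo[k])
                vec = centroids[pos[nearest]] - centroids[pos[c]]
            else:
                vec = np.zeros(centroids.shape[1])
        else:
            vec = centroids[pos[c]] - centroids[pos[parent[c]]]
        nrm = np.linalg.norm(vec)
        direction[pos[c]] = vec / nrm if nrm > 0 else 0.0

    pt = np.empty(len(clusters))
    for c in uniq:
        c = int(c)
        mask = clusters == c
        offsets = embedding[mask] - centroids[pos[c]]
        proj = offsets @ direction[pos[c]]
        pt[mask] = geo[c] + proj
    pt = np.maximum(pt, 0.0)
    root_mask = clusters == int(root)
    pt[root_mask] -= pt[root_mask].min()
    pt = np.maximum(pt, 0.0)
    if cell_ids is None:
        cell_ids = np.arange(len(clusters))
    graph.pseudotime = pd.Series(pt, index=pd.Index(cell_ids, name="cell_id"), name="pseudotime")
    return graph


def terminal_fate_report(
    graph: TrajectoryGraph,
    cell_meta: pd.DataFrame,
    flag_ratio: float = 2.0,
) -> pd.DataFrame:
    """Per-condition occupancy of the tree's leaf clusters.

    For each leaf, the fraction of each condition's cells assigned to that
    cluster; a leaf is flagged for a condition when its fraction exceeds every
    other condition's by ``flag_ratio``.
    """
    clusters = graph.cell_clusters
    cond = cell_meta["condition"].to_numpy()
    conditions = list(pd.unique(cond))
    rows = []
    for leaf in graph.leaves():
        fracs = {}
        for c in conditions:
            mask = cond == c
            fracs[c] = float((clusters[mask] == leaf).mean()) if mask.any() else 0.0
        best = max(fracs, key=fracs.get)
        others = [v for k, v in fracs.items() if k != best]
        flagged = best if fracs[best] > flag_ratio * max(others + [0.0]) and fracs[best] > 0 else ""
        rows.append({"leaf_cluster": leaf, **{f"frac_{c}": fracs[c] for c in conditions},
                     "flagged_for": flagged})
    return pd.DataFrame(rows)
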