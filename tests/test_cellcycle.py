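import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from esostrata import cellcycle as cc
from esostrata import embedding as em
from esostrata import strata as st
from esostrata.io import NormalizedMatrix
from esostrata.synthetic import default_cycle_genes


def _norm_from(values, gene_ids):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=values,
        cell_ids=np.array([f"c{i}" for i in range(values.shape[0])], dtype=object),
        gene_ids=np.array(gene_ids, dtype=object),
    )


# ------------------------------------------------------------ phase scoring
def test_all_zero_expression_scores_zero_phase_g1():
    genes = default_cycle_genes("S")[:3] + default_cycle_genes("G2M")[:3] + ["x1", "x2"]
    norm = _norm_from(np.zeros((5, 8)), genes)
    out = cc.phase_scores(norm, seed=0)
    assert (out["s_score"] == 0).all()
    assert (out["g2m_score"] == 0).all()
    assert (out["phase"] == "G1/G0").all()


def test_phase_call_rule():
    s = np.array([-0.1, 0.4, 0.1, 0.3, 0.0])
    g = np.array([-0.3, 0.1, 0.5, 0.3, 0.0])
    out = cc.call_phase(s, g)
    # both non-positive -> G1/G0; argmax of positive scores; exact tie -> S
    assert list(out) == ["G1/G0", "S", "G2M", "S", "G1/G0"]


def test_engineered_programs_called_correctly():
    s_genes = default_cycle_genes("S")[:2]
    g2m_genes = default_cycle_genes("G2M")[:2]
    genes = s_genes + g2m_genes + [f"x{i}" for i in range(20)]
    vals = np.ones((3, 24))
    vals[0, :4] = 0.2  # cycle genes below bin-mates -> G1/G0
    vals[1, :2] = 3.0  # S program up
    vals[2, 2:4] = 3.0  # G2M program up
    norm = _norm_from(vals, genes)
    out = cc.phase_scores(norm, n_bins=1, n_ctrl=10, seed=0)
    assert out.loc["c0", "phase"] == "G1/G0"
    assert out.loc["c1", "phase"] == "S"
    assert out.loc["c2", "phase"] == "G2M"


def test_missing_all_phase_genes_errors():
    norm = _norm_from(np.ones((3, 2)), ["a", "b"])
    with pytest.raises(ValueError, match="no phase genes"):
        cc.phase_scores(norm)


def test_planted_programs_recovered(default_dataset, default_norm):
    truth = default_dataset["truth"]
    out = cc.phase_scores(default_norm, seed=1)
    for phase in ("S", "G2M"):
        mask = (truth["phase"] == phase).to_numpy()
        recall = (out["phase"].to_numpy()[mask] == phase).mean()
        assert recall >= 0.9


# ------------------------------------------------------------ root selection
def _toy_root_setup():
    # clusters 0,1 basal; 2 suprabasal. 0 is G1-dominated, 1 is S-dominated.
    clusters = np.repeat([0, 1, 2], 10)
    strata = pd.DataFrame(
        {"stratum": ["basal", "basal", "suprabasal"]}, index=pd.Index([0, 1, 2], name="cluster")
    )
    phase = np.array(["G1/G0"] * 8 + ["S"] * 2 + ["S"] * 9 + ["G2M"] + ["G1/G0"] * 10)
    phases = pd.DataFrame({"phase": phase})
    # adjacency: cluster 0 tightly linked to cluster 1
    adj = sp.lil_matrix((30, 30))
    for i in range(10):
        adj[i, 10 + i] = 1
        adj[10 + i, i] = 1
    return clusters, strata, phases, adj.tocsr()


def test_single_qualifying_basal_cluster_is_root():
    clusters, strata, phases, adj = _toy_root_setup()
    assert cc.select_root(clusters, strata, phases, adj) == 0


def test_manual_override_wins():
    clusters, strata, phases, adj = _toy_root_setup()
    assert cc.select_root(clusters, strata, phases, adj, override=2) == 2


def test_root_invariant_to_cluster_relabeling():
    clusters, strata, phases, adj = _toy_root_setup()
    # relabel 0 -> 5
    relabeled = np.where(clusters == 0, 5, clusters)
    strata2 = strata.rename(index={0: 5})
    assert cc.select_root(relabeled, strata2, phases, adj) == 5


def test_no_g1_basal_cluster_errors():
    clusters, strata, phases, adj = _toy_root_setup()
    phases_bad = phases.copy()
    phases_bad.loc[:9, "phase"] = "G2M"
    with pytest.raises(ValueError, match="override"):
        cc.select_root(clusters, strata, phases_bad, adj)


def test_planted_root_recovered(default_dataset, default_norm, truth_clusters, default_embedding):
    truth = default_dataset["truth"]
    labels = truth_clusters["labels"]
    x = st.cluster_marker_mean(default_norm, labels, "Krt5")
    y = st.cluster_marker_mean(default_norm, labels, "Krtdap")
    strata = st.classify_strata(x, y)
    phases = cc.phase_scores(default_norm, seed=1)
    adj = em.knn_graph(default_embedding["pca"], k=20)
    root = cc.select_root(labels, strata, phases, adj)
    assert truth_clusters["inv"][root] == "B1"


# ------------------------------------------------------- tree and pseudotime
def test_cells_at_root_centroid_have_zero_pseudotime():
    emb = np.array([[0.0, 0], [0, 0], [5, 0], [5, 0], [10, 0], [10, 0]])
    clusters = np.array([0, 0, 1, 1, 2, 2])
    g = cc.build_tree_and_pseudotime(emb, clusters, root=0)
    assert g.pseudotime.iloc[0] == 0.0
    assert g.pseudotime[clusters == 0].min() == 0.0


def test_collinear_centroids_ordered_along_path():
    rng = np.random.default_rng(0)
    emb = np.vstack([
        rng.normal(scale=0.1, size=(20, 2)) + [0, 0],
        rng.normal(scale=0.1, size=(20, 2)) + [5, 0],
        rng.normal(scale=0.1, size=(20, 2)) + [10, 0],
    ])
    clusters = np.repeat([0, 1, 2], 20)
    g = cc.build_tree_and_pseudotime(emb, clusters, root=0)
    assert g.pseudotime[clusters == 2].mean() > g.pseudotime[clusters == 1].mean()
    assert (g.pseudotime >= 0).all()


def test_geodesics_match_networkx_oracle(default_embedding, truth_clusters):
    import networkx as nx

    labels = truth_clusters["labels"]
    g = cc.build_tree_and_pseudotime(default_embedding["umap"], labels, root=0)
    dist = g.centroid_distance()
    G = nx.Graph()
    for u, v, w in g.edges:
        G.add_edge(u, v, weight=w)
    oracle = nx.single_source_dijkstra_path_length(G, 0)
    for c, d in dist.items():
        assert d == pytest.approx(oracle[c], abs=1e-9)


def test_pseudotime_monotone_along_root_to_leaf_paths(default_embedding, truth_clusters):
    labels = truth_clusters["labels"]
    g = cc.build_tree_and_pseudotime(default_embedding["umap"], labels, root=0)
    dist = g.centroid_distance()
    parent = g.parents()
    for leaf in g.leaves():
        node = leaf
        while node != g.root:
            assert dist[node] >= dist[parent[node]] - 1e-12
            node = parent[node]


def test_unknown_root_rejected():
    emb = np.zeros((4, 2))
    with pytest.raises(ValueError, match="root"):
        cc.build_tree_and_pseudotime(emb, np.array([0, 0, 1, 1]), root=7)


# -------------------------------------------------------- terminal fates
def test_fate_report_fractions_and_flags():
    emb = np.vstack([
        np.zeros((10, 2)), np.ones((10, 2)) * [5, 0], np.ones((10, 2)) * [10, 0],
    ])
    clusters = np.repeat([0, 1, 2], 10)
    meta = pd.DataFrame({
        "condition": ["control"] * 15 + ["ESCC"] * 15,
    })
    g = cc.build_tree_and_pseudotime(emb, clusters, root=0)
    rep = cc.terminal_fate_report(g, meta)
    leaf = rep.set_index("leaf_cluster").loc[2]
    # cluster 2 = cells 20-29, all ESCC: private leaf, flagged for ESCC
    assert leaf["frac_control"] == pytest.approx(0.0)
    assert leaf["frac_ESCC"] == pytest.approx(10 / 15)
    assert leaf["flagged_for"] == "ESCC"
    # absent condition -> fraction 0
    meta2 = pd.DataFrame({"condition": ["control"] * 30})
    rep2 = cc.terminal_fate_report(g, meta2)
    assert "frac_control" in rep2.columns


def test_escc_private_leaf_flagged(default_dataset, default_embedding, truth_clusters):
    truth = default_dataset["truth"]
    labels = truth_clusters["labels"]
    root = truth_clusters["popmap"]["B1"]
    g = cc.build_tree_and_pseudotime(default_embedding["umap"], labels, root=root)
    rep = cc.terminal_fate_report(g, default_dataset["counts"].cell_meta)
    inv = truth_clusters["inv"]
    flagged = {inv[int(r.leaf_cluster)]: r.flagged_for for r in rep.itertuples()}
    # EoE-expanded suprabasal populations appear as EoE-flagged leaves when terminal
    assert any(v == "EoE" for v in flagged.values()) or any(v == "ESCC" for v in flagged.values())
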