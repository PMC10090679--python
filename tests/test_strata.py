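import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from esostrata import strata as st
from esostrata.io import NormalizedMatrix


def _norm_from(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(
        values=values,
        cell_ids=np.array([f"c{i}" for i in range(values.shape[0])], dtype=object),
        gene_ids=np.array(gene_ids, dtype=object),
    )


# ------------------------------------------------------------- marker means
def test_marker_mean_basics():
    norm = _norm_from([[0, 1], [0, 2], [5, 0]], gene_ids=["Krt5", "Krtdap"])
    clusters = np.array([0, 0, 1])
    means = st.cluster_marker_mean(norm, clusters, "Krt5")
    assert means[0] == 0.0
    assert means[1] == 5.0
    assert st.cluster_marker_mean(norm, clusters, "Krtdap")[0] == 1.5


def test_marker_mean_agrees_with_streaming_oracle():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(10_000, 1)) ** 2
    clusters = rng.integers(0, 7, size=10_000)
    norm = _norm_from(vals, gene_ids=["Krt5"])
    means = st.cluster_marker_mean(norm, clusters, "Krt5")
    # independent one-pass accumulation
    acc, cnt = {}, {}
    for v, c in zip(vals[:, 0], clusters):
        acc[c] = acc.get(c, 0.0) + v
        cnt[c] = cnt.get(c, 0) + 1
    for c in acc:
        assert means[c] == pytest.approx(acc[c] / cnt[c], rel=1e-10)


def test_marker_mean_missing_gene_suggests_candidates():
    norm = _norm_from([[1.0]], gene_ids=["Krt5"])
    with pytest.raises(KeyError, match="Krt5"):
        st.cluster_marker_mean(norm, np.array([0]), "krt5")


# --------------------------------------------------------- strip classifier
@pytest.mark.parametrize(
    "x, y, expected",
    [
        (1.0, 1.0, "suprabasal"),
        (1.0, 0.5, "basal"),
        (0.2, 0.9, "superficial"),
        (0.0, 0.3, "suprabasal"),  # boundary belongs to the strip
        (0.3, 0.0, "suprabasal"),
    ],
)
def test_classify_strata_examples(x, y, expected):
    calls = st.classify_strata({0: x}, {0: y})
    assert calls.loc[0, "stratum"] == expected


def test_classify_partitions_all_clusters():
    rng = np.random.default_rng(1)
    xs = {i: float(v) for i, v in enumerate(rng.uniform(0, 2, 50))}
    ys = {i: float(v) for i, v in enumerate(rng.uniform(0, 2, 50))}
    calls = st.classify_strata(xs, ys)
    assert len(calls) == 50
    assert calls["stratum"].isin(["basal", "suprabasal", "superficial"]).all()


@settings(max_examples=200, derandomize=True)
@given(
    x=st_.floats(-5, 5, allow_nan=False),
    y=st_.floats(-5, 5, allow_nan=False),
    hw=st_.floats(0, 2, allow_nan=False),
)
def test_swap_symmetry_maps_basal_to_superficial(x, y, hw):
    params = st.StripParams(half_width=hw)
    fwd = st.classify_strata({0: x}, {0: y}, params).loc[0, "stratum"]
    rev = st.classify_strata({0: y}, {0: x}, params).loc[0, "stratum"]
    swap = {"basal": "superficial", "superficial": "basal", "suprabasal": "suprabasal"}
    assert rev == swap[fwd]


def test_monotone_in_y():
    # increasing y with x fixed never moves a cluster toward basal
    order = {"basal": 0, "suprabasal": 1, "superficial": 2}
    x = 1.0
    prev = -1
    for y in np.linspace(0, 2.5, 60):
        stratum = st.classify_strata({0: x}, {0: float(y)}).loc[0, "stratum"]
        assert order[stratum] >= prev
        prev = order[stratum]


def test_nonfinite_means_rejected():
    with pytest.raises(ValueError, match="finite"):
        st.classify_strata({0: np.nan}, {0: 1.0})


# -------------------------------------------------------------- dot plot
def test_dotplot_uniform_gene_zscores_zero():
    vals = np.ones((9, 1))
    norm = _norm_from(vals, gene_ids=["Krt5"])
    clusters = np.repeat([0, 1, 2], 3)
    out = st.dotplot_stats(norm, clusters, panel=["Krt5"])
    assert (out["zscore"] == 0).all()
    assert out["frac_nonzero"].between(0, 1).all()


def test_dotplot_zscores_match_direct_formula():
    vals = np.array([[1.0], [1.0], [2.0], [2.0], [6.0], [6.0]])
    norm = _norm_from(vals, gene_ids=["Krt5"])
    clusters = np.repeat([0, 1, 2], 2)
    out = st.dotplot_stats(norm, clusters, panel=["Krt5"]).set_index("cluster")
    means = np.array([1.0, 2.0, 6.0])
    z = (means - means.mean()) / means.std()
    for c in (0, 1, 2):
        assert out.loc[c, "zscore"] == pytest.approx(z[c])
    # per-gene z-scores across clusters: mean 0, sd 1
    assert out["zscore"].mean() == pytest.approx(0, abs=1e-12)
    assert out["zscore"].std(ddof=0) == pytest.approx(1)


def test_dotplot_missing_gene_skipped_single_cluster_warns():
    norm = _norm_from([[1.0], [2.0]], gene_ids=["Krt5"])
    with pytest.warns(UserWarning):
        out = st.dotplot_stats(norm, np.array([0, 0]), panel=["Krt5", "Nope1"])
    assert set(out["gene"]) == {"Krt5"}
    assert (out["zscore"] == 0).all()


# ------------------------------------------------------------- top markers
def test_exclusive_gene_ranks_first():
    vals = np.zeros((6, 3))
    vals[:3, 0] = 2.0  # g0 exclusive to cluster 0
    vals[:, 1] = 1.0   # uniform
    norm = _norm_from(vals)
    clusters = np.repeat([0, 1], 3)
    top = st.top_markers_per_cluster(norm, clusters, k=2)
    assert top[0][0] == "g0"


def test_k_larger_than_gene_count_returns_all():
    vals = np.random.default_rng(2).normal(size=(6, 3))
    top = st.top_markers_per_cluster(_norm_from(vals), np.repeat([0, 1], 3), k=10)
    assert len(top[0]) == 3


def test_planted_signature_genes_recovered(default_norm, truth_clusters):
    labels = truth_clusters["labels"]
    inv = truth_clusters["inv"]
    top = st.top_markers_per_cluster(default_norm, labels, k=5)
    hits = 0
    for c, genes in top.items():
        pop = inv[c]
        hits += any(g.startswith(f"{pop}_sig") for g in genes)
    assert hits >= 12  # at least 12 of 13 populations led by own signature genes
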