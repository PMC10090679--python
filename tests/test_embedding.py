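import numpy as np
import pytest

from esostrata import embedding as em
from esostrata.io import NormalizedMatrix

from conftest import tiny_count_matrix


def _norm_from(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=values,
        cell_ids=np.array([f"c{i}" for i in range(values.shape[0])], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(values.shape[1])], dtype=object),
    )


# ------------------------------------------------------------- normalization
def test_normalize_zero_count_maps_to_zero():
    cm = tiny_count_matrix([[0, 3], [1, 2]])
    norm = em.normalize_log10(cm)
    assert norm.values[0, 0] == 0.0


def test_normalize_equal_totals_scale_factor_one():
    cm = tiny_count_matrix([[9, 1], [1, 9]])  # both totals 10 = median
    norm = em.normalize_log10(cm)
    assert norm.values[0, 0] == pytest.approx(1.0)  # log10(1 + 9)


def test_normalize_removes_per_cell_depth_differences():
    # two cells with proportional counts land on identical normalized rows
    base = np.array([[4, 2, 0, 6], [8, 4, 0, 12], [3, 3, 3, 3]])
    norm = em.normalize_log10(tiny_count_matrix(base))
    assert np.allclose(norm.values[0], norm.values[1])


def test_normalize_scale_homogeneity_by_direct_computation():
    # doubling every count doubles the size-factor-scaled counts exactly
    # (the median target doubles with the data)
    rng = np.random.default_rng(0)
    base = rng.poisson(2.0, size=(30, 20)) + 1
    a = em.normalize_log10(tiny_count_matrix(base))
    b = em.normalize_log10(tiny_count_matrix(base * 2))
    assert np.allclose(10 ** b.values - 1, 2 * (10 ** a.values - 1))


def test_normalize_zero_total_cell_warns_and_stays_zero():
    cm = tiny_count_matrix([[0, 0], [2, 3]])
    with pytest.warns(UserWarning, match="zero total"):
        norm = em.normalize_log10(cm)
    assert (norm.values[0] == 0).all()


# ---------------------------------------------------------------- regression
def test_regress_constant_covariate_is_identity():
    norm = _norm_from(np.random.default_rng(1).normal(size=(10, 4)))
    out = em.regress_covariate(norm, np.array(["a"] * 10))
    assert np.allclose(out.values, norm.values)


def test_regress_equalizes_batch_means():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(40, 6))
    x[:20] += 3.0  # batch shift
    batches = np.array(["b1"] * 20 + ["b2"] * 20)
    out = em.regress_covariate(_norm_from(x), batches)
    m1 = out.values[:20].mean(axis=0)
    m2 = out.values[20:].mean(axis=0)
    assert np.allclose(m1, m2)


def test_regress_recovers_preshift_correlation_structure():
    rng = np.random.default_rng(3)
    latent = rng.normal(size=(200, 1))
    clean = latent @ rng.normal(size=(1, 8)) + 0.3 * rng.normal(size=(200, 8))
    shifted = clean.copy()
    shifted[:100] += rng.normal(size=8) * 4  # per-gene batch offset
    batches = np.array(["b1"] * 100 + ["b2"] * 100)
    out = em.regress_covariate(_norm_from(shifted), batches)
    corr_clean = np.corrcoef(clean.T)
    corr_reg = np.corrcoef(out.values.T)
    assert np.abs(corr_clean - corr_reg).max() < 0.1


# ----------------------------------------------------------------------- PCA
def test_pca_rank2_data_has_two_informative_components():
    rng = np.random.default_rng(4)
    basis = rng.normal(size=(2, 10))
    coords = rng.normal(size=(50, 2))
    x = coords @ basis
    scores = em.run_pca(_norm_from(x), n_components=5, seed=0)
    variances = scores.var(axis=0)
    assert variances[2:].max() < 1e-10 * variances[0]
    assert np.all(np.diff(variances) <= 1e-9)  # non-increasing


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(20, 10))
    scores = em.run_pca(_norm_from(x), n_components=3, seed=0)
    # oracle: eigenvectors of the covariance of the standardized matrix
    z = (x - x.mean(0)) / x.std(0)
    w, v = np.linalg.eigh(np.cov(z.T, bias=True))
    order = np.argsort(w)[::-1]
    oracle = z @ v[:, order[:3]]
    for j in range(3):
        assert np.allclose(np.abs(scores[:, j]), np.abs(oracle[:, j]), atol=1e-8)


def test_pca_reduces_components_with_warning():
    x = np.random.default_rng(6).normal(size=(5, 4))
    with pytest.warns(UserWarning, match="reducing"):
        scores = em.run_pca(_norm_from(x), n_components=50, seed=0)
    assert scores.shape[1] <= 4


# ---------------------------------------------------------------------- UMAP
def test_umap_deterministic_and_separates_blobs():
    rng = np.random.default_rng(7)
    blob1 = rng.normal(size=(60, 5))
    blob2 = rng.normal(size=(60, 5)) + 20.0
    x = np.vstack([blob1, blob2])
    e1 = em.run_umap(x, seed=0)
    e2 = em.run_umap(x, seed=0)
    assert np.array_equal(e1, e2)
    c1, c2 = e1[:60].mean(0), e1[60:].mean(0)
    radius = np.linalg.norm(e1[:60] - c1, axis=1).mean()
    assert np.linalg.norm(c1 - c2) > radius


def test_umap_clamps_neighbors_for_tiny_input():
    x = np.random.default_rng(8).normal(size=(8, 3))
    with pytest.warns(UserWarning, match="clamped"):
        out = em.run_umap(x, seed=0, n_neighbors=15)
    assert out.shape == (8, 2)


# ----------------------------------------------------------------- clustering
def test_cluster_recovers_three_planted_blobs():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(9)
    pts = np.vstack([rng.normal(size=(50, 2)) + [0, 0],
                     rng.normal(size=(50, 2)) + [30, 0],
                     rng.normal(size=(50, 2)) + [0, 30]])
    truth = np.repeat([0, 1, 2], 50)
    out = em.cluster_cells(pts, resolution=3e-3, seed=0)
    assert out.n_clusters == 3
    assert adjusted_rand_score(truth, out.labels) == 1.0


def test_cluster_resolution_limit_single_cluster():
    rng = np.random.default_rng(10)
    pts = rng.normal(size=(80, 2))  # one connected blob
    out = em.cluster_cells(pts, resolution=1e-9, seed=0)
    assert out.n_clusters == 1


def test_cluster_deterministic_and_complete():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(100, 2))
    a = em.cluster_cells(pts, seed=4)
    b = em.cluster_cells(pts, seed=4)
    assert np.array_equal(a.labels, b.labels)
    assert len(a.labels) == 100
    assert set(a.labels) == set(range(a.n_clusters))  # contiguous from 0


def test_cluster_labels_sorted_by_descending_size():
    rng = np.random.default_rng(12)
    pts = np.vstack([rng.normal(size=(80, 2)), rng.normal(size=(20, 2)) + 50])
    out = em.cluster_cells(pts, seed=0)
    sizes = np.bincount(out.labels)
    assert np.all(np.diff(sizes) <= 0)
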