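import numpy as np
import pytest
from scipy.spatial.distance import cdist

from methsig import (NoKneeError, ParameterError, ValidationError,
                     dbscan_cluster, estimate_knee, knn_distance_curve,
                     remove_noise)
from methsig.denoise import BORDER, CORE, NOISE_TYPE
from conftest import make_gene_matrix
from _references import canonical_labels, naive_dbscan


def test_knn_curve_hand_example():
    pts = np.array([[0.0], [1.0], [2.0], [10.0]])
    np.testing.assert_allclose(knn_distance_curve(pts, 1), [1, 1, 1, 8])


def test_knn_curve_duplicates_give_leading_zeros():
    pts = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0], [6.0, 6.0]])
    curve = knn_distance_curve(pts, 1)
    assert curve[0] == 0.0 and curve[1] == 0.0


def test_knn_curve_matches_bruteforce(rng):
    pts = rng.normal(size=(50, 4))
    for k in (1, 3, 7):
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        expected = np.sort(np.sort(d, axis=1)[:, k - 1])
        np.testing.assert_allclose(knn_distance_curve(pts, k), expected)


def test_knn_curve_parameter_errors():
    pts = np.zeros((3, 2))
    with pytest.raises(ParameterError):
        knn_distance_curve(pts, 0)
    with pytest.raises(ParameterError):
        knn_distance_curve(pts, 3)


def test_knee_jump_curve_reports_raw_distance_at_jump():
    k = estimate_knee([0, 1, 2, 3, 4, 20, 40])
    assert k.eps == 20.0
    assert k.knee_index == 5
    assert k.scaled_distances[0] == 0.0 and k.scaled_distances[-1] == 1.0


def test_knee_linear_curve_has_no_knee():
    with pytest.raises(NoKneeError):
        estimate_knee([0, 1, 2, 3, 4])


def test_knee_constant_curve_instructs_manual_eps():
    with pytest.raises(NoKneeError, match="manual"):
        estimate_knee([2.0, 2.0, 2.0])


def test_knee_scaled_convention_and_threshold():
    k = estimate_knee([0, 1, 2, 3, 4, 20, 40], eps_scale="scaled")
    assert k.eps == 0.5
    # a lower threshold fires earlier on a convex curve
    k2 = estimate_knee([0, 1, 2, 4, 8, 16, 32], threshold=0.5)
    assert k2.knee_index <= estimate_knee([0, 1, 2, 4, 8, 16, 32],
                                          threshold=1.5).knee_index
    with pytest.raises(ParameterError):
        estimate_knee([0, 1, 2], threshold=0)
    with pytest.raises(ValidationError):
        estimate_knee([3, 2, 1])


def test_dbscan_line_example_core_border_noise():
    pts = np.array([[0.0], [1.0], [2.0], [10.0]])
    res = dbscan_cluster(pts, eps=1.1, min_pts=3)
    assert list(res.point_type) == [BORDER, CORE, BORDER, NOISE_TYPE]
    assert list(res.labels) == [0, 0, 0, -1]


def test_dbscan_everything_core_when_eps_huge():
    pts = np.random.default_rng(0).normal(size=(12, 3))
    res = dbscan_cluster(pts, eps=1e3, min_pts=1)
    assert (res.point_type == CORE).all()
    assert set(res.labels) == {0}


def test_dbscan_2d_example_five_core_one_noise():
    pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5], [10, 10]], float)
    res = dbscan_cluster(pts, eps=1.5, min_pts=5)
    assert list(res.point_type[:5]) == [CORE] * 5
    assert res.point_type[5] == NOISE_TYPE
    assert res.n_clusters == 1


def test_dbscan_invariants_on_random_data(rng):
    pts = rng.normal(size=(80, 5))
    res = dbscan_cluster(pts, eps=2.0, min_pts=4)
    n_core = (res.point_type == CORE).sum()
    n_border = (res.point_type == BORDER).sum()
    n_noise = (res.point_type == NOISE_TYPE).sum()
    assert n_core + n_border + n_noise == len(pts)
    assert ((res.labels == -1) == (res.point_type == NOISE_TYPE)).all()
    d = cdist(pts, pts)
    for i in np.flatnonzero(res.point_type == BORDER):
        core_near = [j for j in range(len(pts))
                     if res.point_type[j] == CORE and d[i, j] <= 2.0]
        assert core_near, "border point without a core neighbor"
    for c in range(res.n_clusters):
        assert (res.point_type[res.labels == c] == CORE).any()


def test_dbscan_validation_errors():
    with pytest.raises(ValidationError):
        dbscan_cluster(np.array([[np.inf, 0.0]]), 1.0, 1)
    with pytest.raises(ParameterError):
        dbscan_cluster(np.zeros((3, 2)), -1.0, 1)
    with pytest.raises(ParameterError):
        dbscan_cluster(np.zeros((3, 2)), 1.0, 0)


def test_dbscan_permutation_invariance(rng):
    pts = rng.normal(size=(60, 3))
    res = dbscan_cluster(pts, eps=1.5, min_pts=4)
    perm = rng.permutation(60)
    res_p = dbscan_cluster(pts[perm], eps=1.5, min_pts=4)
    # point types are exactly order-invariant here; labels up to relabel
    assert list(res_p.point_type) == [res.point_type[i] for i in perm]
    a = canonical_labels(res.labels[perm])
    b = canonical_labels(res_p.labels)
    assert (a == b).all()


def test_remove_noise_accounting_and_strict_mode(rng):
    values = rng.uniform(size=(30, 6))
    g = make_gene_matrix(values)
    res = dbscan_cluster(values, eps=0.8, min_pts=4)
    clean = remove_noise(g, res)
    dropped = (res.point_type == NOISE_TYPE).sum()
    assert clean.n_genes + dropped == g.n_genes
    strict = remove_noise(g, res, keep_border=False)
    assert strict.n_genes == (res.point_type == CORE).sum()
    with pytest.raises(ValidationError):
        remove_noise(make_gene_matrix(values[:10]), res)


def test_no_noise_result_is_identity(rng):
    values = rng.normal(size=(20, 4)) * 0.01 + 0.5
    g = make_gene_matrix(values)
    res = dbscan_cluster(values, eps=5.0, min_pts=2)
    clean = remove_noise(g, res)
    assert clean.gene_ids == g.gene_ids
    np.testing.assert_array_equal(clean.values, g.values)


def test_dbscan_equals_reference_on_small_instances(rng):
    for _ in range(15):
        n = int(rng.integers(10, 60))
        dim = int(rng.integers(1, 6))
        pts = rng.normal(size=(n, dim))
        eps = float(rng.uniform(0.3, 2.5))
        min_pts = int(rng.integers(1, 8))
        res = dbscan_cluster(pts, eps, min_pts)
        ref_labels, ref_types = naive_dbscan(pts, eps, min_pts)
        assert list(res.point_type) == list(ref_types)
        assert (canonical_labels(res.labels) == canonical_labels(ref_labels)).all()
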