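import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from methsig import (ParameterError, ValidationError, colors_for_sizes,
                     cut_modules, pick_power, scale_free_r2,
                     tom_from_adjacency, tom_from_matrix)
from methsig.netmodules import GREY, Network
from conftest import make_gene_matrix
from _references import naive_average_linkage


def modular_matrix(rng, sizes=(30, 20), rho=0.9, n_s=20):
    """Planted correlated blocks with independent background noise."""
    rows = []
    for size in sizes:
        f = rng.standard_normal(n_s)
        for _ in range(size):
            rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n_s))
    return make_gene_matrix(np.array(rows))


def test_tom_hand_values_complete_and_empty_graph():
    ones = np.ones((3, 3))
    tom = tom_from_adjacency(ones)
    iu = np.triu_indices(3, 1)
    np.testing.assert_allclose(tom[iu], 1.0, atol=1e-12)
    tom0 = tom_from_adjacency(np.zeros((3, 3)))
    np.testing.assert_allclose(tom0[iu], 0.0, atol=1e-12)
    np.testing.assert_allclose(np.diag(tom0), 1.0)


def test_tom_hand_value_single_shared_neighbor():
    a = np.array([[0.0, 0.5, 0.5],
                  [0.5, 0.0, 0.0],
                  [0.5, 0.0, 0.0]])
    tom = tom_from_adjacency(a)
    # TOM_12 = (0 + 0.5) / (min(1.0, 0.5) + 1 - 0.5) = 0.5
    assert tom[0, 1] == pytest.approx(0.5, abs=1e-12)
    # TOM_23 = (0.5*0.5 + 0) / (0.5 + 1 - 0) = 1/6
    assert tom[1, 2] == pytest.approx(0.25 / 1.5, abs=1e-12)


def test_tom_equals_adjacency_when_rest_disconnected():
    for x in (0.2, 0.7, 1.0):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = x
        tom = tom_from_adjacency(a)
        assert tom[0, 1] == pytest.approx(x, abs=1e-12)


def test_tom_bounds_and_symmetry_on_random_network(rng):
    g = make_gene_matrix(rng.normal(size=(25, 12)))
    net = tom_from_matrix(g, 6)
    assert (net.tom >= 0).all() and (net.tom <= 1).all()
    np.testing.assert_allclose(net.tom, net.tom.T)
    np.testing.assert_allclose(np.diag(net.tom), 1.0)
    np.testing.assert_allclose(np.diag(net.adjacency), 1.0)


def test_constant_gene_vector_rejected():
    vals = np.vstack([np.full(8, 0.5), np.random.default_rng(0).normal(size=(3, 8))])
    with pytest.raises(ValidationError):
        tom_from_matrix(make_gene_matrix(vals), 6)


def test_average_linkage_matches_cubic_reference(rng):
    n = 30
    pts = rng.normal(size=(n, 5))
    d = squareform(np.ascontiguousarray(
        np.linalg.norm(pts[:, None] - pts[None, :], axis=2)), checks=False)
    z = linkage(d, method="average")
    heights = z[:, 2]
    assert (np.diff(heights) >= -1e-12).all()  # monotone merges
    ref_heights, ref_cut = naive_average_linkage(squareform(d))
    np.testing.assert_allclose(np.sort(heights), np.sort(ref_heights), rtol=1e-10)
    for t in np.quantile(heights, [0.2, 0.5, 0.8]):
        flat = fcluster(z, t=t, criterion="distance")
        got = {frozenset(np.flatnonzero(flat == c)) for c in np.unique(flat)}
        assert got == ref_cut(t)


def test_cut_modules_two_planted_blocks(rng):
    g = modular_matrix(rng, sizes=(30, 20), rho=0.9)
    net = tom_from_matrix(g, 6)
    assign = cut_modules(net, min_module_size=10, cut_height=0.99)
    assert assign.module_sizes == {"turquoise": 30, "blue": 20}
    # membership matches the construction exactly
    assert set(assign.genes_in("turquoise")) == set(g.gene_ids[:30])
    assert set(assign.genes_in("blue")) == set(g.gene_ids[30:])


def test_cut_modules_limits_and_errors(rng):
    g = make_gene_matrix(rng.normal(size=(8, 10)))
    net = tom_from_matrix(g, 2)
    singletons = cut_modules(net, min_module_size=1, cut_height=0.0)
    assert sorted(singletons.module_sizes.values()) == [1] * 8
    assert not (singletons.colors == GREY).any()
    with pytest.raises(ParameterError):
        cut_modules(net, min_module_size=9)
    with pytest.raises(ParameterError):
        cut_modules(net, min_module_size=2, cut_height=1.5)


def test_small_branches_go_grey_or_merge(rng):
    # two strong blocks plus a few unrelated genes below the size floor
    g = modular_matrix(rng, sizes=(15, 12), rho=0.95)
    noise = make_gene_matrix(rng.normal(size=(4, 20)), prefix="N")
    combined = make_gene_matrix(np.vstack([g.values, noise.values]))
    net = tom_from_matrix(combined, 6)
    assign = cut_modules(net, min_module_size=10, cut_height=0.99)
    sizes = sorted(assign.module_sizes.values(), reverse=True)
    assert sizes[0] >= 15 and sizes[1] >= 12
    assert all(s >= 10 for s in assign.module_sizes.values())


def test_colors_follow_decreasing_size():
    sizes = [83, 39, 31, 28, 27, 21]
    assert colors_for_sizes(sizes) == [
        "turquoise", "blue", "brown", "yellow", "green", "red"]
    # pure function of sizes: permutation-invariant up to alignment
    perm = [21, 83, 28, 39, 27, 31]
    colors = colors_for_sizes(perm)
    assert colors[perm.index(83)] == "turquoise"
    assert colors[perm.index(21)] == "red"


def test_pick_power_boundary_and_determinism(rng):
    g = modular_matrix(rng, sizes=(20, 15), rho=0.8)
    trivial = pick_power(g, fit_target=0.0)
    assert trivial.power == 1 and trivial.met_target
    sel1 = pick_power(g)
    sel2 = pick_power(g)
    assert sel1.power == sel2.power
    assert len(sel1.table) == 20
    with pytest.raises(ValidationError):
        pick_power(make_gene_matrix(rng.normal(size=(2, 10))))


def test_scale_free_r2_on_power_law_degrees(rng):
    # genuine power-law degrees fit well; constant degrees do not
    k = (1.0 - rng.random(4000)) ** (-1.0 / 1.5)  # Pareto tail
    assert scale_free_r2(k) > 0.8
    assert scale_free_r2(np.full(100, 3.0)) == 0.0
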