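import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import polygamma

from methsig import (EBHyper, GroupDesign, ValidationError, estimate_prior,
                     fit_group_stats, moderated_t_test, run_diffmeth,
                     voom_weights)
from methsig.diffmeth import D0_CAP, design_from_matrix, inverse_trigamma
from conftest import make_gene_matrix


def two_group_design(n1=3, n2=3):
    return GroupDesign([f"S{j + 1:03d}" for j in range(n1)],
                       [f"S{j + 1:03d}" for j in range(n1, n1 + n2)])


def test_design_validation():
    with pytest.raises(ValidationError):
        GroupDesign(["a"], ["b", "c"])
    with pytest.raises(ValidationError):
        GroupDesign(["a", "b"], ["b", "c"])
    d = two_group_design()
    assert d.n1 == 3 and d.n2 == 3 and d.residual_df == 4


def test_group_stats_hand_example():
    # case = [3,4,5], control = [1,2,3] -> contrast 2, pooled variance 1
    g = make_gene_matrix([[3, 4, 5, 1, 2, 3]])
    stats = fit_group_stats(g, two_group_design())
    assert stats.loc[0, "beta_hat"] == pytest.approx(2.0)
    assert stats.loc[0, "s_g_sq"] == pytest.approx(1.0)
    assert stats.loc[0, "d_g"] == 4


def test_group_stats_symmetry_and_weight_scale_invariance(rng):
    vals = rng.normal(0.5, 0.1, size=(40, 6))
    g = make_gene_matrix(vals)
    design = two_group_design()
    identical = make_gene_matrix(np.tile(vals[:, :3], 2))
    assert np.allclose(fit_group_stats(identical, design)["beta_hat"], 0.0)
    w = rng.uniform(0.5, 2.0, size=vals.shape)
    a = fit_group_stats(g, design, w)
    b = fit_group_stats(g, design, 2.0 * w)
    for col in ("beta_hat", "s_g_sq"):
        np.testing.assert_allclose(a[col], b[col])


def test_voom_weights_contract(rng):
    design = two_group_design(4, 4)
    few = make_gene_matrix(rng.uniform(0.2, 0.8, size=(5, 8)))
    with pytest.warns(UserWarning, match="unit weights"):
        w = voom_weights(few, design)
    assert (w == 1.0).all()
    g = make_gene_matrix(rng.uniform(0.2, 0.8, size=(200, 8)))
    w = voom_weights(g, design)
    assert np.isfinite(w).all() and (w > 0).all()


def test_voom_weights_near_uniform_for_homoscedastic_log_data(rng):
    # constant-variance data on the log2 scale, mapped back to the value
    # scale the transform expects
    design = two_group_design(4, 4)
    y = rng.normal(8.0, 0.4, size=(2000, 8))
    v = (2.0 ** y - 0.5) / 1e6
    g = make_gene_matrix(np.clip(v, 1e-9, None))
    w = voom_weights(g, design)
    rel = w / w.mean()
    assert rel.max() <= 1.2 and rel.min() >= 0.8


def test_inverse_trigamma_against_bisection(rng):
    for x in rng.uniform(1e-4, 50.0, size=100):
        y = inverse_trigamma(float(x))
        y_ref = brentq(lambda t: polygamma(1, t) - x, 1e-8, 1e9, xtol=1e-12)
        assert y == pytest.approx(y_ref, rel=1e-6)


def test_prior_recovery_from_simulated_variances():
    rng = np.random.default_rng(0)
    d0_true, s0_true, d_g, n = 4.0, 1.0, 4, 5000
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n)
    s2 = sigma2 * rng.chisquare(d_g, size=n) / d_g
    prior = estimate_prior(s2, d_g)
    assert 3.0 <= prior.d0 <= 5.0
    assert 0.9 <= prior.s0_sq <= 1.1


def test_prior_degenerate_cases():
    with pytest.raises(ValidationError):
        estimate_prior(np.zeros(100), 4)
    with pytest.raises(ValidationError):
        estimate_prior(np.ones(5), 4)
    prior = estimate_prior(np.ones(100), 4)  # identical variances
    assert prior.d0 == D0_CAP


def test_moderated_t_reduces_to_pooled_t_without_shrinkage():
    g = make_gene_matrix([[3, 4, 5, 1, 2, 3]])
    design = two_group_design()
    stats = fit_group_stats(g, design)
    prior = EBHyper(d0=1e-9, s0_sq=123.0)  # negligible prior weight
    out = moderated_t_test(stats, prior, design)
    assert out.loc[0, "t_tilde"] == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), rel=1e-6)
    assert out.loc[0, "t_tilde"] == pytest.approx(2.449, abs=5e-4)


def test_moderated_t_cap_limit_uses_prior_variance():
    g = make_gene_matrix([[3, 4, 5, 1, 2, 3]])
    design = two_group_design()
    stats = fit_group_stats(g, design)
    prior = EBHyper(d0=D0_CAP, s0_sq=4.0)
    out = moderated_t_test(stats, prior, design)
    assert out.loc[0, "s_tilde_sq"] == pytest.approx(4.0, rel=1e-4)
    assert out.loc[0, "t_tilde"] == pytest.approx(
        2.0 / (2.0 * np.sqrt(2.0 / 3.0)), rel=1e-4)


def test_zero_contrast_is_never_called():
    g = make_gene_matrix([[1, 2, 3, 1, 2, 3]])
    design = two_group_design()
    stats = fit_group_stats(g, design)
    out = moderated_t_test(stats, EBHyper(1.0, 1.0), design)
    assert out.loc[0, "t_tilde"] == 0.0
    assert out.loc[0, "p_value"] == pytest.approx(1.0)
    assert not out.loc[0, "dm"]
    assert out.loc[0, "direction"] == "hypo"  # hyper iff contrast > 0


def test_posterior_variance_between_sample_and_prior(rng):
    g = make_gene_matrix(rng.normal(0.5, 0.2, size=(300, 6)))
    design = two_group_design()
    stats = fit_group_stats(g, design)
    prior = estimate_prior(stats["s_g_sq"].to_numpy(), design.residual_df)
    out = moderated_t_test(stats, prior, design)
    lo = np.minimum(out["s_g_sq"], prior.s0_sq)
    hi = np.maximum(out["s_g_sq"], prior.s0_sq)
    assert ((out["s_tilde_sq"] >= lo - 1e-12) & (out["s_tilde_sq"] <= hi + 1e-12)).all()


def test_shrinkage_monotonicity_of_t(rng):
    g = make_gene_matrix(rng.normal(0.5, 0.2, size=(50, 6)))
    design = two_group_design()
    stats = fit_group_stats(g, design)
    s0 = float(stats["s_g_sq"].median())
    t_none = moderated_t_test(stats, EBHyper(1e-9, s0), design)["t_tilde"]
    t_mid = moderated_t_test(stats, EBHyper(4.0, s0), design)["t_tilde"]
    t_full = moderated_t_test(stats, EBHyper(D0_CAP, s0), design)["t_tilde"]
    lo = np.minimum(np.abs(t_none), np.abs(t_full))
    hi = np.maximum(np.abs(t_none), np.abs(t_full))
    assert ((np.abs(t_mid) >= lo - 1e-9) & (np.abs(t_mid) <= hi + 1e-9)).all()


def test_recall_increases_with_effect_size():
    rng = np.random.default_rng(7)
    n_genes, shift_genes = 400, 80
    recalls = []
    for effect in (0.05, 0.15, 0.3):
        vals = rng.normal(0.5, 0.1, size=(n_genes, 12))
        vals[:shift_genes, :6] += effect
        g = make_gene_matrix(np.clip(vals, 0, 1), groups="half")
        out = run_diffmeth(g)
        recalls.append(out.loc[:shift_genes - 1, "dm"].mean())
    assert recalls[0] <= recalls[1] <= recalls[2]
    assert recalls[2] >= 0.8


def test_bh_flag_is_more_conservative(rng):
    vals = rng.normal(0.5, 0.1, size=(300, 10))
    vals[:30, :5] += 0.15
    g = make_gene_matrix(np.clip(vals, 0, 1), groups="half")
    raw = run_diffmeth(g)
    bh = run_diffmeth(g, fdr="bh")
    assert bh["dm"].sum() <= raw["dm"].sum()
    assert "q_value" in bh.columns


def test_design_from_matrix_roundtrip(rng):
    g = make_gene_matrix(rng.uniform(size=(12, 8)), groups="half")
    d = design_from_matrix(g)
    assert d.n1 == 4 and d.n2 == 4
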