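"""Robust score tests against dense reference implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import romgei as rg
from romgei.nullmodel import fit_null_lm
from romgei.sandwich import (
    SkipVariant,
    bread_interaction,
    bread_joint,
    build_design,
    estimate_effects,
    icb_test,
    lm_icb_test,
    marginal_test,
    meat_joint,
    model_based_test,
    rom_test,
    sandwich_parts,
    two_step_test,
)

from oracles import dense_strategy, hc0_score_test


def _vd(toy_cohort, j=0):
    g = toy_cohort["panel"].genotypes[:, j].astype(float)
    return build_design(g, toy_cohort["x1"][:, None], exposure_names=["x1"])


def test_build_design_basics(toy_cohort):
    g = np.array([0.0, 1.0, 2.0])
    vd = build_design(g, np.ones((3, 1)))
    np.testing.assert_array_equal(vd.K[:, 0], g)  # unit exposure: K = g
    vd = build_design(np.zeros(3), np.ones((3, 1)))
    assert np.all(vd.W == 0)
    # missing genotype mean-imputed before products
    g = np.array([0.0, 1.0, np.nan, 2.0, 1.0])
    e = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    vd = build_design(g, e[:, None])
    assert vd.g[2] == pytest.approx(1.0)
    assert vd.K[2, 0] == pytest.approx(3.0)


def test_build_design_guards_exposure_membership(toy_cohort):
    g = toy_cohort["panel"].genotypes[:, 0].astype(float)
    E = pd.DataFrame({"bmi": toy_cohort["x1"]})
    with pytest.raises(ValueError, match="bmi"):
        build_design(g, E, null_columns=["intercept", "x1", "x2"])
    build_design(g, E, null_columns=["intercept", "x1", "x2"], override=True)


@pytest.mark.parametrize("j", [0, 3, 8])
def test_bread_effects_and_meat_match_dense_oracle(toy_cohort, toy_fit, toy_sigma, j):
    vd = _vd(toy_cohort, j)
    y, X = toy_fit.spec.y, toy_fit.spec.X
    clusters = toy_cohort["km"].clusters
    zeta_o, cov_J, cov_I, T_J, T_I = dense_strategy(
        y, X, toy_sigma, vd.g, vd.K, clusters, "robust"
    )
    B_J = bread_joint(toy_fit, vd)
    np.testing.assert_allclose(
        B_J, np.linalg.inv(vd.W.T @ np.linalg.inv(toy_sigma) @ vd.W
             - vd.W.T @ np.linalg.inv(toy_sigma) @ X
             @ np.linalg.inv(X.T @ np.linalg.inv(toy_sigma) @ X)
             @ X.T @ np.linalg.inv(toy_sigma) @ vd.W),
        rtol=1e-8,
    )
    np.testing.assert_allclose(estimate_effects(toy_fit, vd), zeta_o, rtol=1e-8)
    parts = sandwich_parts(toy_fit, vd, clusters)
    np.testing.assert_allclose(parts.bread_joint @ parts.meat_joint @ parts.bread_joint,
                               cov_J, rtol=1e-8)


def test_bread_interaction_schur_identity(toy_cohort, toy_fit):
    vd = _vd(toy_cohort)
    B_J = bread_joint(toy_fit, vd)
    B_I = bread_interaction(toy_fit, vd)
    # inverse-partition identity: the K-block of B_J equals B_I
    np.testing.assert_allclose(B_I, B_J[1:, 1:], rtol=1e-10)
    parts = sandwich_parts(toy_fit, vd, toy_cohort["km"].clusters)
    np.testing.assert_array_equal(parts.meat_int, parts.meat_joint[1:, 1:])


@pytest.mark.parametrize(
    "strategy", ["RoM", "LMM-MB", "LMM-ICB", "Two-step-ICB", "LM-ICB"]
)
def test_every_strategy_matches_dense_reference(toy_cohort, toy_fit, toy_sigma, strategy):
    vd = _vd(toy_cohort, 2)
    km = toy_cohort["km"]
    y, X = toy_fit.spec.y, toy_fit.spec.X
    if strategy == "RoM":
        res = rom_test(toy_fit, vd, km.clusters)
        exp = dense_strategy(y, X, toy_sigma, vd.g, vd.K, km.clusters, "robust")
    elif strategy == "LMM-MB":
        res = model_based_test(toy_fit, vd)
        exp = dense_strategy(y, X, toy_sigma, vd.g, vd.K, None, "model")
    elif strategy == "LMM-ICB":
        res = icb_test(toy_fit, vd)
        exp = dense_strategy(y, X, toy_sigma, vd.g, vd.K, None, "robust")
    elif strategy == "Two-step-ICB":
        res = two_step_test(y, X, {"kinship": km.relationship_blocks()},
                            km.clusters, vd, step1_fit=toy_fit)
        e = toy_fit.lambdas["residual"] * toy_fit.R_tilde
        lmfit = fit_null_lm(e, X)
        sig = lmfit.lambdas["residual"] * np.eye(km.n)
        exp = dense_strategy(e, X, sig, vd.g, vd.K, None, "robust")
    else:  # LM-ICB
        res = lm_icb_test(y, X, vd)
        lmfit = fit_null_lm(y, X)
        sig = lmfit.lambdas["residual"] * np.eye(km.n)
        exp = dense_strategy(y, X, sig, vd.g, vd.K, None, "robust")
    _, _, _, T_J, T_I = exp
    assert res.skip_reason is None
    assert res.T_J == pytest.approx(T_J, rel=1e-8)
    assert res.T_I == pytest.approx(T_I, rel=1e-8)
    assert res.df_J == 2 and res.df_I == 1
    assert 0 < res.p_J <= 1 and 0 < res.p_I <= 1


def test_icb_equals_rom_with_singleton_clusters(toy_cohort, toy_fit):
    vd = _vd(toy_cohort, 5)
    singles = [np.array([i]) for i in range(toy_fit.spec.n)]
    a = rom_test(toy_fit, vd, singles)
    b = icb_test(toy_fit, vd)
    assert a.T_J == pytest.approx(b.T_J, rel=1e-12)
    assert a.T_I == pytest.approx(b.T_I, rel=1e-12)


def test_hc0_reduction_exact(unrelated_cohort):
    """Unrelated samples, identity working covariance, singleton clusters:
    the sandwich equals the brute-force HC0 linear-model score test."""
    y, X, g, x = (unrelated_cohort[k] for k in ("y", "X", "g", "x"))
    vd = build_design(g, x[:, None])
    lmfit = fit_null_lm(y, X)
    res = icb_test(lmfit, vd)
    T_J, T_I = hc0_score_test(y, X, vd.W)
    assert res.T_J == pytest.approx(T_J, rel=1e-10)
    assert res.T_I == pytest.approx(T_I, rel=1e-10)


def test_marginal_test_matches_dense_score(toy_cohort, toy_fit, toy_sigma):
    g = toy_cohort["panel"].genotypes[:, 1].astype(float)
    from oracles import dense_pieces

    _, P, _, _, R = dense_pieces(toy_fit.spec.y, toy_fit.spec.X, toy_sigma)
    expect = (g @ R) ** 2 / (g @ P @ g)
    res = marginal_test(toy_fit, g)
    assert res.T_J == pytest.approx(expect, rel=1e-8)
    assert res.df_J == 1
    # orthogonal genotype: zero statistic
    res0 = marginal_test(toy_fit, np.zeros_like(g))
    assert res0.skip_reason == "zero genetic variance"


def test_monomorphic_and_collinear_variants_are_skipped(toy_cohort, toy_fit):
    n = toy_fit.spec.n
    mono = build_design(np.zeros(n), toy_cohort["x1"][:, None])
    with pytest.raises(SkipVariant, match="zero genetic variance"):
        bread_joint(toy_fit, mono)
    res = rom_test(toy_fit, mono, toy_cohort["km"].clusters)
    assert res.skip_reason == "zero genetic variance"
    assert np.isnan(res.T_J)
    # constant exposure -> K proportional to g -> singular design
    g = toy_cohort["panel"].genotypes[:, 0].astype(float)
    prop = build_design(g, np.full((n, 1), 2.0))
    res = rom_test(toy_fit, prop, toy_cohort["km"].clusters)
    assert res.skip_reason is not None


def test_zero_residuals_give_zero_meat(toy_cohort, toy_fit):
    vd = _vd(toy_cohort)
    fit = toy_fit
    saved = fit.R_tilde
    try:
        fit.R_tilde = np.zeros_like(saved)
        M = meat_joint(fit, vd, toy_cohort["km"].clusters)
        assert np.all(M == 0)
    finally:
        fit.R_tilde = saved


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_statistics_invariant_to_exposure_rescaling(scale):
    """Rescaling the exposure (and its covariate column) must leave both
    test statistics unchanged."""
    ped = rg.build_pedigree(8, 0)
    km = rg.compute_kinship(ped)
    rng = np.random.default_rng(55)
    x = rng.standard_normal(km.n)
    y = 0.5 * x + rng.standard_normal(km.n)
    g = rng.binomial(2, 0.4, km.n).astype(float)

    def run(xs):
        X = np.column_stack([np.ones(km.n), xs])
        spec = rg.NullModelSpec.from_kinship(y, X, km)
        fit = rg.fit_null_reml(spec, tol=1e-10)
        vd = build_design(g, xs[:, None])
        return rom_test(fit, vd, km.clusters)

    a, b = run(x), run(scale * x)
    assert a.T_J == pytest.approx(b.T_J, rel=1e-5)
    assert a.T_I == pytest.approx(b.T_I, rel=1e-5)


def test_scan_reproduces_single_variant_calls(toy_cohort, toy_fit):
    km = toy_cohort["km"]
    G = toy_cohort["panel"].genotypes
    E = toy_cohort["x1"][:, None]
    res = rg.scan(
        toy_fit, G, E,
        strategies=("RoM", "LMM-MB", "LMM-ICB", "Two-step-ICB", "LM-ICB", "marginal"),
        block_size=7,
    )
    y, X = toy_fit.spec.y, toy_fit.spec.X
    comp = {"kinship": km.relationship_blocks()}
    for j in [0, 4, 11, 24]:
        vd = _vd(toy_cohort, j)
        singles = {
            "RoM": rom_test(toy_fit, vd, km.clusters),
            "LMM-MB": model_based_test(toy_fit, vd),
            "LMM-ICB": icb_test(toy_fit, vd),
            "Two-step-ICB": two_step_test(y, X, comp, km.clusters, vd, step1_fit=toy_fit),
            "LM-ICB": lm_icb_test(y, X, vd),
            "marginal": marginal_test(toy_fit, vd.g),
        }
        for strat, single in singles.items():
            row = res[(res.variant_index == j) & (res.strategy == strat)].iloc[0]
            if single.skip_reason is not None:
                assert row.skip_reason == single.skip_reason
                continue
            assert row.T_J == pytest.approx(single.T_J, rel=1e-9)
            if strat != "marginal":
                assert row.T_I == pytest.approx(single.T_I, rel=1e-9)
                assert row.beta_main == pytest.approx(single.beta_hat, rel=1e-9)


def test_scan_invariant_to_block_size(toy_cohort, toy_fit):
    G = toy_cohort["panel"].genotypes
    E = toy_cohort["x1"][:, None]
    a = rg.scan(toy_fit, G, E, strategies=("RoM", "Two-step-ICB"), block_size=3)
    b = rg.scan(toy_fit, G, E, strategies=("RoM", "Two-step-ICB"), block_size=25)
    np.testing.assert_allclose(a.T_J.to_numpy(), b.T_J.to_numpy(), rtol=1e-12)
    np.testing.assert_allclose(a.T_I.to_numpy(), b.T_I.to_numpy(), rtol=1e-12)


def test_scan_empty_and_unknown_strategy(toy_cohort, toy_fit):
    E = toy_cohort["x1"][:, None]
    empty = rg.scan(toy_fit, np.empty((toy_fit.spec.n, 0)), E)
    assert len(empty) == 0
    with pytest.raises(ValueError, match="unknown strategies"):
        rg.scan(toy_fit, toy_cohort["panel"].genotypes, E, strategies=("bogus",))


def test_rom_pvalues_calibrated_under_correct_null():
    """Independent samples, correctly specified null: RoM p-values are
    uniform (KS at alpha=0.001) and the inflation factor is near 1."""
    rng = np.random.default_rng(77)
    n = 2000
    x = rng.standard_normal(n)
    y = 1.0 + 0.4 * x + rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    lmfit = fit_null_lm(y, X)
    V = 20000
    G = rng.binomial(2, rng.uniform(0.1, 0.5, V), size=(n, V)).astype(np.int8)
    res = rg.scan(lmfit, G, x[:, None], strategies=("RoM",), block_size=4096)
    from scipy import stats as ss

    for col, df in (("p_I", 1), ("p_J", 2)):
        p = res[col].dropna().to_numpy()
        assert ss.kstest(p, "uniform").pvalue > 0.001
        lam = rg.genomic_inflation_from_pvalues(p, df)
        assert 0.95 < lam < 1.05
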