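"""REML fitting and the implicit projection operator."""

import numpy as np
import pytest
import scipy.optimize

import romgei as rg
from romgei.nullmodel import (
    NullModelSpec,
    fit_null_lm,
    random_slope_component,
    repeated_measures_clusters,
)

from oracles import dense_pieces, dense_reml_loglik


@pytest.fixture(scope="module")
def tiny():
    """N=20 cohort (5 nuclear families) with a family-correlated trait,
    so the kinship variance component has an interior REML optimum."""
    ped = rg.build_pedigree(5, 0)
    km = rg.compute_kinship(ped)
    rng = np.random.default_rng(36)
    x = rng.standard_normal(km.n)
    X = np.column_stack([np.ones(km.n), x])
    r = np.concatenate([np.full(4, v) for v in rng.standard_normal(5)])
    y = 0.3 * x + r + 0.7 * rng.standard_normal(km.n)
    spec = NullModelSpec.from_kinship(y, X, km)
    return {"km": km, "X": X, "y": y, "spec": spec}


def _dense_sigma(km, lam_k, lam_r):
    return lam_k * km.to_sparse(2.0).toarray() + lam_r * np.eye(km.n)


def test_lm_degenerates_to_ols():
    rng = np.random.default_rng(32)
    n = 50
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ [1.0, 2.0] + rng.standard_normal(n)
    fit = fit_null_lm(y, X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.alpha, beta, rtol=1e-10)
    rss = np.sum((y - X @ beta) ** 2)
    assert fit.lambdas["residual"] == pytest.approx(rss / (n - 2))


def test_reml_matches_dense_criterion_at_optimum(tiny):
    fit = rg.fit_null_reml(tiny["spec"], tol=1e-10)
    assert fit.converged
    lam = fit.lambdas
    # 1. the package loglik equals the dense criterion at lambda_hat
    dense_ll = dense_reml_loglik(
        tiny["y"], tiny["X"], _dense_sigma(tiny["km"], lam["kinship"], lam["residual"])
    )
    assert fit.loglik == pytest.approx(dense_ll, abs=1e-8)
    # 2. lambda_hat maximises the dense criterion (independent optimizer)
    res = scipy.optimize.minimize(
        lambda t: -dense_reml_loglik(
            tiny["y"], tiny["X"], _dense_sigma(tiny["km"], np.exp(t[0]), np.exp(t[1]))
        ),
        np.log([lam["kinship"] + 0.3, lam["residual"] + 0.3]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    assert -res.fun <= dense_ll + 1e-7
    np.testing.assert_allclose(np.exp(res.x), [lam["kinship"], lam["residual"]], rtol=1e-3)


def test_scaled_residuals_equal_dense_projection(tiny):
    fit = rg.fit_null_reml(tiny["spec"])
    lam = fit.lambdas
    sigma = _dense_sigma(tiny["km"], lam["kinship"], lam["residual"])
    _, P, _, _, R = dense_pieces(tiny["y"], tiny["X"], sigma)
    np.testing.assert_allclose(fit.scaled_residuals(), P @ tiny["y"], atol=1e-8)
    np.testing.assert_allclose(fit.scaled_residuals(), R, atol=1e-8)
    # covariate orthogonality
    assert np.abs(tiny["X"].T @ fit.R_tilde).max() < 1e-10 * np.linalg.norm(tiny["y"])


def test_y_in_covariate_space_gives_zero_residuals(tiny):
    y = tiny["X"] @ np.array([2.0, -1.0])
    spec = NullModelSpec.from_kinship(y, tiny["X"], tiny["km"])
    fit = rg.fit_null_reml(spec)
    # the scaled residuals are whitened by a floored variance, so compare
    # on the conditional-residual (data) scale
    assert np.abs(fit.conditional_residuals()).max() < 1e-8 * np.abs(y).max()


def test_apply_projection_properties(tiny):
    fit = rg.fit_null_reml(tiny["spec"])
    lam = fit.lambdas
    sigma = _dense_sigma(tiny["km"], lam["kinship"], lam["residual"])
    _, P, _, _, _ = dense_pieces(tiny["y"], tiny["X"], sigma)
    # annihilates covariates
    assert np.abs(fit.apply_projection(tiny["X"])).max() < 1e-10
    # dense agreement on a random matrix
    rng = np.random.default_rng(33)
    V = rng.standard_normal((tiny["km"].n, 4))
    np.testing.assert_allclose(fit.apply_projection(V), P @ V, atol=1e-8)
    # symmetric-idempotent in the Sigma inner product
    np.testing.assert_allclose(P @ sigma @ P, P, atol=1e-8)


def test_reml_invariant_to_covariate_reparameterization(tiny):
    fit = rg.fit_null_reml(tiny["spec"], tol=1e-9)
    A = np.array([[2.0, 1.0], [0.0, -3.0]])
    spec2 = NullModelSpec.from_kinship(tiny["y"], tiny["X"] @ A, tiny["km"])
    fit2 = rg.fit_null_reml(spec2, tol=1e-9)
    for k in fit.lambdas:
        assert fit.lambdas[k] == pytest.approx(fit2.lambdas[k], rel=1e-4, abs=1e-8)
    np.testing.assert_allclose(fit.R_tilde, fit2.R_tilde, atol=1e-6)


def test_rank_deficient_design_names_columns(tiny):
    X = np.column_stack([tiny["X"], tiny["X"][:, 1]])
    spec = NullModelSpec.from_kinship(
        tiny["y"], X, tiny["km"], column_names=["intercept", "x", "x_again"]
    )
    with pytest.raises(ValueError, match="x_again|x"):
        rg.fit_null_reml(spec)


def test_repeated_measures_random_intercept():
    rng = np.random.default_rng(34)
    n_subj, n_obs = 120, 3
    subj = np.repeat(np.arange(n_subj), n_obs)
    u = rng.standard_normal(n_subj) * 1.0
    y = 1.0 + u[subj] + rng.standard_normal(len(subj))
    clusters, blocks = repeated_measures_clusters(subj)
    spec = NullModelSpec(
        y=y, X=np.ones((len(y), 1)), components={"subject": blocks}, clusters=clusters
    )
    fit = rg.fit_null_reml(spec)
    assert fit.converged
    assert 0.4 < fit.lambdas["subject"] < 1.8
    assert 0.6 < fit.lambdas["residual"] < 1.5


def test_random_slope_component_construction():
    km = rg.compute_kinship(rg.build_pedigree(2, 0))
    expo = np.arange(km.n, dtype=float)
    blocks = random_slope_component(km.relationship_blocks(), expo, km.clusters)
    for blk, base, idx in zip(blocks, km.relationship_blocks(), km.indices):
        d = expo[idx]
        np.testing.assert_allclose(blk, base * np.outer(d, d))
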