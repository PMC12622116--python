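"""Shared fixtures: a small family cohort with a misspecified null fit."""

import numpy as np
import pytest

import romgei as rg
from romgei.nullmodel import NullModelSpec


@pytest.fixture(scope="session")
def toy_cohort():
    """10 nuclear families (N=40) with exposures, trait and genotypes."""
    ped = rg.build_pedigree(10, 0)
    km = rg.compute_kinship(ped)
    x1, x2 = rg.simulate_exposures(km, 11)
    alphas = rg.calibrate_effects()
    tr = rg.simulate_trait(km, x1, x2, alphas, 12)
    panel = rg.simulate_genotypes(ped, rg.draw_mafs(25, 13), 14)
    return {"ped": ped, "km": km, "x1": x1, "x2": x2, "trait": tr, "panel": panel}


@pytest.fixture(scope="session")
def toy_fit(toy_cohort):
    """Misspecified-null REML fit on the toy cohort."""
    c = toy_cohort
    X = rg.null_design(c["x1"], c["x2"])
    spec = NullModelSpec.from_kinship(
        c["trait"].y, X, c["km"], column_names=["intercept", "x1", "x2"]
    )
    fit = rg.fit_null_reml(spec)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def toy_sigma(toy_cohort, toy_fit):
    """Dense working covariance implied by the toy fit."""
    km = toy_cohort["km"]
    lam = toy_fit.lambdas
    sigma = lam["kinship"] * km.to_sparse(scale=2.0).toarray()
    sigma += lam["residual"] * np.eye(km.n)
    return sigma


@pytest.fixture(scope="session")
def unrelated_cohort():
    """60 unrelated singletons with an exposure-bearing linear trait."""
    rng = np.random.default_rng(21)
    n = 60
    x = rng.standard_normal(n)
    y = 0.5 + 0.3 * x + rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    g = rng.binomial(2, 0.3, size=n).astype(float)
    return {"y": y, "X": X, "x": x, "g": g}
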