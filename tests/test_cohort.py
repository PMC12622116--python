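"""Simulation engine: gene dropping, exposures, trait calibration."""

import numpy as np
import pytest

import romgei as rg


def _allele_sets(g):
    return {0: {0}, 1: {0, 1}, 2: {1}}[g]


def test_mendelian_consistency_exhaustive():
    ped = rg.build_pedigree(40, 10)
    panel = rg.simulate_genotypes(ped, rg.draw_mafs(30, 1), 2)
    fa, mo = ped.parent_indices()
    G = panel.genotypes
    for i in np.flatnonzero(fa >= 0):
        for j in range(G.shape[1]):
            possible = {
                a + b
                for a in _allele_sets(G[fa[i], j])
                for b in _allele_sets(G[mo[i], j])
            }
            assert G[i, j] in possible


def test_founder_genotypes_follow_hwe():
    ped = rg.build_pedigree(5000, 0)  # 10,000 founders
    maf = 0.3
    panel = rg.simulate_genotypes(ped, np.array([maf]), 3)
    founders = [i for i, m in enumerate(ped.members) if m.is_founder]
    g = panel.genotypes[founders, 0]
    n = len(founders)
    expected = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    for k in range(3):
        phat = np.mean(g == k)
        se = np.sqrt(expected[k] * (1 - expected[k]) / n)
        assert abs(phat - expected[k]) < 3 * se


def test_sib_genotype_correlation_is_half():
    ped = rg.build_pedigree(8000, 0)
    panel = rg.simulate_genotypes(ped, np.array([0.25]), 4)
    g = panel.genotypes[:, 0].astype(float)
    sib1 = g[2::4]
    sib2 = g[3::4]
    r = np.corrcoef(sib1, sib2)[0, 1]
    assert abs(r - 0.5) < 3 / np.sqrt(len(sib1))


def test_monomorphic_parents_give_monomorphic_offspring():
    ped = rg.build_pedigree(50, 0)
    panel = rg.simulate_genotypes(ped, np.array([1e-9]), 5)
    assert np.all(panel.genotypes == 0)


def test_invalid_maf_rejected():
    ped = rg.build_pedigree(1, 0)
    with pytest.raises(ValueError):
        rg.simulate_genotypes(ped, np.array([0.7]), 1)


def test_genotype_blocks_reproducible_and_streamable():
    ped = rg.build_pedigree(20, 5)
    mafs = rg.draw_mafs(100, 6)
    a = np.concatenate([b for _, b in rg.genotype_blocks(ped, mafs, 7, 32)], axis=1)
    b = np.concatenate([b for _, b in rg.genotype_blocks(ped, mafs, 7, 32)], axis=1)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (ped.n_individuals, 100)


def test_exposure_covariance_structure():
    km = rg.compute_kinship(rg.build_pedigree(8000, 0))
    x1, x2 = rg.simulate_exposures(km, 8)
    # parent-child covariance of the heritable exposure: 2 * phi = 0.5
    cov_pc = np.mean(x1[0::4] * x1[2::4])
    assert abs(cov_pc - 0.5) < 3 * 1.2 / np.sqrt(8000)
    assert abs(np.var(x1) - 1.0) < 0.05  # diag(2 Psi) = 1
    assert abs(np.var(x2) - 2.0) < 0.1
    # x1 independent across families
    assert abs(np.mean(x1[0::4] * np.roll(x1[0::4], 1))) < 3 / np.sqrt(8000)


def test_singleton_pedigree_gives_iid_exposure():
    # degenerate: families of unrelated founders only
    from romgei.pedigree import KinshipModel

    n = 5000
    km = KinshipModel(
        [f"s{i}" for i in range(n)],
        [np.array([[0.5]])] * n,
        [np.array([i]) for i in range(n)],
        n,
    )
    x1, _ = rg.simulate_exposures(km, 9)
    assert abs(np.var(x1) - 1.0) < 0.07


def test_effect_calibration_closed_form():
    al = rg.calibrate_effects((0.0, 0.0, 0.0, 0.0))
    assert al.as_array().tolist() == [0, 0, 0, 0]
    assert al.var_y == 2.0

    al = rg.calibrate_effects()
    assert al.var_y == pytest.approx(2.0 / 0.7)
    # the quadratic x1 term explains exactly 5% of trait variance
    assert 2 * al.a2**2 / al.var_y == pytest.approx(0.05)
    with pytest.raises(ValueError):
        rg.calibrate_effects((0.5, 0.3, 0.2, 0.1))


def test_simulated_variance_shares_match_targets():
    km = rg.compute_kinship(rg.build_pedigree(3000, 500))
    x1, x2 = rg.simulate_exposures(km, 10)
    al = rg.calibrate_effects()
    tr = rg.simulate_trait(km, x1, x2, al, 11)
    vy = np.var(tr.y)
    assert vy == pytest.approx(al.var_y, rel=0.05)
    shares = [
        np.var(al.a1 * x1) / vy,
        np.var(al.a2 * x1**2) / vy,
        np.var(al.a3 * x2) / vy,
        np.var(al.a4 * x2**2) / vy,
    ]
    np.testing.assert_allclose(shares, [0.1, 0.05, 0.1, 0.05], atol=0.012)


def test_trait_determinism_and_degenerate_case():
    km = rg.compute_kinship(rg.build_pedigree(100, 0))
    x1, x2 = rg.simulate_exposures(km, 12)
    zero = rg.Alphas(0, 0, 0, 0, 2.0)
    a = rg.simulate_trait(km, x1, x2, zero, 13)
    b = rg.simulate_trait(km, x1, x2, zero, 13)
    np.testing.assert_array_equal(a.y, b.y)
    # no polygenic effect: y = 1 + eps
    c = rg.simulate_trait(km, x1, x2, zero, 14, polygenic_scale=0.0)
    assert abs(np.mean(c.y) - 1.0) < 3 / np.sqrt(km.n)
    assert abs(np.var(c.y) - 1.0) < 0.15


def test_null_design_columns():
    x1 = np.array([1.0, -1.0])
    x2 = np.array([0.5, 0.5])
    assert rg.null_design(x1, x2).shape == (2, 3)
    X = rg.null_design(x1, x2, correct=True)
    assert X.shape == (2, 5)
    np.testing.assert_array_equal(X[:, 3], x1**2)
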