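import numpy as np
import pytest

from gfblup import (ArchitectureSpec, DesignSpec, SNPPartition, build_grm,
                    gls_blup_oracle, predict_validation, simulate_genotypes,
                    simulate_phenotype, solve_mme)
from gfblup.exceptions import ParameterError, ValidationError
from gfblup.grm import GRM


def _random_instance(rng, n, n_train, two_comps=False):
    a = rng.normal(size=(n, n))
    g1 = GRM([f"s{i}" for i in range(n)], a @ a.T / n + 0.05 * np.eye(n), 1.0, "c1")
    comps = [(g1, 1.0 + rng.random())]
    if two_comps:
        b = rng.normal(size=(n, n))
        g2 = GRM(g1.sample_ids, b @ b.T / n + 0.05 * np.eye(n), 1.0, "c2")
        comps.append((g2, 0.5 + rng.random()))
    x_full = np.column_stack([np.ones(n), rng.normal(size=n)])
    train = rng.choice(n, size=n_train, replace=False)
    design = DesignSpec.from_training(x_full, train, n)
    y = rng.normal(size=n_train)
    return y, design, comps


def test_hand_solved_three_by_three():
    """y=(1,-1), X=1, Z=I, G=I, lambda=1 gives b=0, u=(0.5,-0.5)."""
    g = GRM(["a", "b"], np.eye(2), 1.0, "g")
    fit = solve_mme(np.array([1.0, -1.0]), DesignSpec(np.ones((2, 1)), np.eye(2)),
                    [(g, 1.0)])
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.u["g"], [0.5, -0.5], atol=1e-12)
    np.testing.assert_array_equal(fit.gebv, fit.u["g"])


def test_mme_gls_equivalence_small_batch():
    """MME solutions equal direct GLS-BLUP on random 1- and 2-GRM instances."""
    rng = np.random.default_rng(7)
    for rep in range(8):
        two = rep % 2 == 1
        y, design, comps = _random_instance(rng, 30, 24, two_comps=two)
        sigma2_e = 0.8
        mme = solve_mme(y, design, [(g, sigma2_e / s2) for g, s2 in comps])
        gls = gls_blup_oracle(y, design, comps, sigma2_e)
        np.testing.assert_allclose(mme.beta, gls.beta, atol=1e-8)
        for k in mme.u:
            np.testing.assert_allclose(mme.u[k], gls.u[k], atol=1e-8)


def test_unphenotyped_individuals_propagate_through_g():
    """GEBVs of zero-Z-column individuals agree between MME and the oracle."""
    rng = np.random.default_rng(11)
    y, design, comps = _random_instance(rng, 12, 10)
    mme = solve_mme(y, design, [(g, 1.0 / s2) for g, s2 in comps])
    gls = gls_blup_oracle(y, design, comps, 1.0)
    np.testing.assert_allclose(mme.gebv, gls.gebv, atol=1e-8)
    assert mme.gebv.size == 12  # defined for every individual in G


def test_infinite_shrinkage_limit():
    """lambda -> 1e8 shrinks u to ~0 and b to the OLS solution."""
    rng = np.random.default_rng(3)
    y, design, comps = _random_instance(rng, 20, 20)
    fit = solve_mme(y, design, [(comps[0][0], 1e8)])
    assert np.linalg.norm(fit.u["c1"]) < 1e-6 * np.linalg.norm(y)
    beta_ols, *_ = np.linalg.lstsq(design.x, y, rcond=None)
    np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)


def test_shrinkage_monotonicity():
    """||u|| is non-increasing in lambda across random instances."""
    rng = np.random.default_rng(23)
    for _ in range(20):
        y, design, comps = _random_instance(rng, 15, 12)
        g = comps[0][0]
        norms = [np.linalg.norm(solve_mme(y, design, [(g, lam)]).u["c1"])
                 for lam in (0.1, 1.0, 10.0, 100.0)]
        assert np.all(np.diff(norms) <= 1e-10)


def test_intercept_shift_invariance():
    """Adding c to y shifts the intercept by c and leaves u unchanged."""
    rng = np.random.default_rng(5)
    y, design, comps = _random_instance(rng, 18, 15)
    f0 = solve_mme(y, design, [(comps[0][0], 2.0)])
    f1 = solve_mme(y + 7.5, design, [(comps[0][0], 2.0)])
    assert f1.beta[0] - f0.beta[0] == pytest.approx(7.5, abs=1e-8)
    np.testing.assert_allclose(f0.u["c1"], f1.u["c1"], atol=1e-8)


def test_model3_gebv_is_sum_of_components():
    rng = np.random.default_rng(9)
    y, design, comps = _random_instance(rng, 16, 13, two_comps=True)
    fit = solve_mme(y, design, [(g, 1.0 / s2) for g, s2 in comps])
    np.testing.assert_array_equal(fit.gebv, fit.u["c1"] + fit.u["c2"])


def test_model3_with_huge_feature_lambda_matches_single_grm():
    """sigma2_t at the floor makes the two-GRM fit collapse onto one GRM."""
    panel, _ = simulate_genotypes(n=100, m=600, n_chrom=3, seed=31)
    part = SNPPartition(600, tm=np.arange(80))
    pheno, _ = simulate_phenotype(panel, part,
                                  ArchitectureSpec(h2=0.4, n_qtl=60), seed=32)
    g_exp = build_grm(panel, part.indices("exp"), "exp")
    g_tm = build_grm(panel, part.indices("tm"), "tm")
    design = DesignSpec.from_training(np.ones((100, 1)), np.arange(100), 100)
    single = solve_mme(pheno.y, design, [(g_exp, 2.0)])
    double = solve_mme(pheno.y, design, [(g_exp, 2.0), (g_tm, 1e10)])
    np.testing.assert_allclose(double.gebv, single.gebv, atol=1e-5)


def test_saturated_fixed_effect():
    """One record with X=1: b = y, u = 0."""
    g = GRM(["a"], np.eye(1), 1.0, "g")
    fit = solve_mme(np.array([3.0]), DesignSpec(np.ones((1, 1)), np.eye(1)),
                    [(g, 1.0)])
    assert fit.beta[0] == pytest.approx(3.0)
    assert fit.u["g"][0] == pytest.approx(0.0, abs=1e-12)


def test_predict_validation_contract():
    rng = np.random.default_rng(13)
    y, design, comps = _random_instance(rng, 10, 8)
    fit = solve_mme(y, design, [(comps[0][0], 1.0)])
    assert predict_validation(fit, []).size == 0
    ids = ["s3", "s1", "s7"]
    vals = predict_validation(fit, ids)
    np.testing.assert_array_equal(vals[::-1], predict_validation(fit, ids[::-1]))
    with pytest.raises(ValidationError):
        predict_validation(fit, ["nope"])


def test_bad_lambda_rejected():
    g = GRM(["a", "b"], np.eye(2), 1.0, "g")
    with pytest.raises(ParameterError):
        solve_mme(np.zeros(2), DesignSpec(np.ones((2, 1)), np.eye(2)), [(g, 0.0)])


def test_high_h2_validation_correlation():
    """In a high-h2 simulation, masked-individual GEBVs track true TBVs."""
    panel, _ = simulate_genotypes(n=400, m=800, n_chrom=4, seed=41)
    part = SNPPartition(800, tm=np.arange(100))
    pheno, truth = simulate_phenotype(
        panel, part, ArchitectureSpec(h2=0.9, n_qtl=150), seed=42)
    g = build_grm(panel)
    rng = np.random.default_rng(43)
    val = rng.choice(400, size=60, replace=False)
    train = np.setdiff1d(np.arange(400), val)
    design = DesignSpec.from_training(np.ones((400, 1)), train, 400)
    fit = solve_mme(pheno.y[train], design, [(g, (1 - 0.9) / 0.9)],
                    sample_ids=panel.samples)
    gebv_val = predict_validation(fit, [panel.samples[i] for i in val])
    r = np.corrcoef(gebv_val, truth.tbv[val])[0, 1]
    assert r > 0.5
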