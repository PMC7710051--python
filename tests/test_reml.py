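import numpy as np
import pytest
from scipy.optimize import minimize

from gfblup import (ArchitectureSpec, SNPPartition, VarianceEstimate, aireml,
                    build_grm, heritability, reml_loglik, simulate_genotypes,
                    simulate_phenotype)
from gfblup.exceptions import ParameterError
from gfblup.reml import round_half_away


def dense_reml_loglik(y, x, v):
    """Independent brute-force evaluation of the restricted log-likelihood."""
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    p = vinv - vinv @ x @ np.linalg.inv(xtvx) @ x.T @ vinv
    return -0.5 * (np.linalg.slogdet(v)[1] + np.linalg.slogdet(xtvx)[1]
                   + float(y @ p @ y))


def grid_reml_oracle(y, x, g, span=(1e-4, 5.0), steps=25):
    """Grid + Nelder-Mead maximization of the REML objective (2 params)."""
    grid = np.geomspace(span[0], span[1], steps)
    best, best_ll = None, -np.inf
    for s2g in grid:
        for s2e in grid:
            ll = reml_loglik(y, x, [g], np.array([s2g, s2e]))
            if ll > best_ll:
                best, best_ll = (s2g, s2e), ll
    res = minimize(lambda t: -reml_loglik(y, x, [g], np.exp(t)),
                   np.log(best), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return np.exp(res.x), -res.fun


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(42)
    n = 60
    panel, _ = simulate_genotypes(n=n, m=400, n_chrom=3, seed=13)
    g = build_grm(panel)
    part = SNPPartition(400, tm=np.arange(40))
    pheno, _ = simulate_phenotype(panel, part,
                                  ArchitectureSpec(h2=0.5, n_qtl=50), seed=14)
    x = np.column_stack([np.ones(n), rng.normal(size=n)])
    return pheno.y, x, g


def test_loglik_matches_dense_evaluation(small_problem):
    """reml_loglik equals direct dense-matrix evaluation of the same formula."""
    y, x, g = small_problem
    y6, x6 = y[:6], x[:6, :1]
    g6 = g.matrix[:6, :6] + 0.5 * np.eye(6)
    theta = np.array([0.8, 1.3])
    from gfblup.grm import GRM
    g6_obj = GRM([f"s{i}" for i in range(6)], g6, 1.0)
    v = theta[0] * g6 + theta[1] * np.eye(6)
    assert reml_loglik(y6, x6, [g6_obj], theta) == pytest.approx(
        dense_reml_loglik(y6, x6, v), abs=1e-9)


def test_loglik_identity_ridge_when_g_is_identity(small_problem):
    """With G = I only the sum sigma2_g + sigma2_E is identified."""
    y, x, _ = small_problem
    eye = np.eye(y.size)
    ll1 = reml_loglik(y, x, [eye], np.array([1.0, 1.0]))
    ll2 = reml_loglik(y, x, [eye], np.array([0.3, 1.7]))
    ll3 = reml_loglik(y, x, [eye], np.array([1.9, 0.1]))
    assert ll1 == pytest.approx(ll2, abs=1e-9)
    assert ll1 == pytest.approx(ll3, abs=1e-9)


def test_scale_equivariance(small_problem):
    """Scaling y by c scales the REML argmax variances by c^2."""
    y, x, g = small_problem
    est1 = aireml(y, x, [g])
    est4 = aireml(2.0 * y, x, [g])
    assert est4.components["all"] == pytest.approx(4 * est1.components["all"],
                                                   rel=1e-3)
    assert est4.sigma2_e == pytest.approx(4 * est1.sigma2_e, rel=1e-3)


def test_aireml_matches_grid_oracle(small_problem):
    """AI-REML finds the same optimum as grid+refinement maximization."""
    y, x, g = small_problem
    est = aireml(y, x, [g])
    theta_oracle, ll_oracle = grid_reml_oracle(y, x, g)
    theta_hat = np.array([est.components["all"], est.sigma2_e])
    assert est.loglik == pytest.approx(ll_oracle, abs=1e-4)
    np.testing.assert_allclose(theta_hat, theta_oracle, rtol=1e-3)


def test_aireml_ascent_and_convergence_record(small_problem):
    y, x, g = small_problem
    est = aireml(y, x, [g], init=np.array([0.05, 2.5]))
    assert est.history[-1] >= est.history[0]
    assert np.all(np.diff(est.history) >= -1e-9)
    assert est.converged and est.n_iter <= 200
    assert set(est.se) == {"all", "e"}


def test_aireml_permutation_invariance(small_problem):
    y, x, g = small_problem
    rng = np.random.default_rng(3)
    perm = rng.permutation(y.size)
    from gfblup.grm import GRM
    gp = GRM([g.sample_ids[i] for i in perm],
             g.matrix[np.ix_(perm, perm)], g.denominator, "all")
    est = aireml(y, x, [g])
    estp = aireml(y[perm], x[perm], [gp])
    assert estp.components["all"] == pytest.approx(est.components["all"], abs=1e-6)
    assert estp.sigma2_e == pytest.approx(est.sigma2_e, abs=1e-6)


def test_h2_zero_simulation_hits_floor():
    """With no genetic signal the genomic component collapses to its floor."""
    panel, _ = simulate_genotypes(n=150, m=300, n_chrom=3, seed=17)
    g = build_grm(panel)
    x = np.ones((150, 1))
    at_floor = 0
    for s in range(10):
        rng = np.random.default_rng(100 + s)
        y = rng.normal(size=150)
        est = aireml(y, x, [g])
        if est.components["all"] < 0.05 * est.sigma2_e:
            at_floor += 1
    assert at_floor >= 8


def test_model3_collapse_to_model1():
    """Duplicated GRMs in the two-component model recover the total variance."""
    panel, _ = simulate_genotypes(n=150, m=500, n_chrom=4, seed=19)
    part = SNPPartition(500, tm=np.arange(100))
    pheno, _ = simulate_phenotype(panel, part,
                                  ArchitectureSpec(h2=0.5, n_qtl=80), seed=20)
    g = build_grm(panel)
    x = np.ones((150, 1))
    est1 = aireml(pheno.y, x, [g], names=["all"])
    from gfblup.grm import GRM
    g2 = GRM(g.sample_ids, g.matrix, g.denominator, "dup")
    est3 = aireml(pheno.y, x, [g, g2], names=["a", "b"])
    total3 = sum(est3.components.values())
    assert total3 == pytest.approx(est1.components["all"], rel=0.02)
    assert est3.sigma2_e == pytest.approx(est1.sigma2_e, rel=0.02)


@pytest.mark.parametrize("comps,s2e,model,expected", [
    ({"all": 913.66}, 1287.6, 1, 0.42),
    ({"mt": 705.05, "t": 171.76}, 1307.3, 3, 0.40),
    ({"all": 50.37}, 77.59, 1, 0.39),
    ({"mt": 0.07, "t": 0.04}, 0.55, 3, 0.17),
    ({"mt": 0.65, "t": 0.000024}, 2.47, 3, 0.21),
    ({"mt": 5.24}, 11.55, 2, 0.31),
    ({"mt": 8.91, "t": 0.63}, 13.64, 3, 0.41),
])
def test_heritability_formulas(comps, s2e, model, expected):
    """The three h2 formulas applied to published-scale variance components."""
    est = VarianceEstimate(comps, s2e, 0.0, 0, True)
    assert heritability(est, model, rounded=True) == pytest.approx(expected)


def test_heritability_boundaries_and_errors():
    est0 = VarianceEstimate({"all": 0.0}, 1.0, 0.0, 0, True)
    assert heritability(est0, 1) == 0.0
    with pytest.raises(ParameterError):
        heritability(est0, 3)
    with pytest.raises(ParameterError):
        heritability(est0, 4)


def test_round_half_away_from_zero():
    assert round_half_away(0.405, 2) == 0.41
    assert round_half_away(0.404999, 2) == 0.40
    assert round_half_away(-0.405, 2) == -0.41
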