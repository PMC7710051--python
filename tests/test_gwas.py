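import numpy as np
import pandas as pd
import pytest

from gfblup import (ArchitectureSpec, SNPPartition, adjust_phenotype,
                    assoc_scan, build_grm, loco_grm_set,
                    significance_thresholds, simulate_genotypes,
                    simulate_phenotype)
from gfblup.exceptions import ParameterError, ValidationError
from gfblup.io import MISSING, GenotypePanel, PhenotypeTable


def _pheno_frame(y, **covs):
    df = pd.DataFrame({"id": [f"i{k}" for k in range(len(y))], "y": y, **covs})
    df["y_missing"] = pd.isna(df["y"])
    df["covariate_missing"] = False
    cats = [c for c in covs if df[c].dtype == object]
    return PhenotypeTable(df, "id", "y", cats, [c for c in covs if c not in cats])


def test_adjust_intercept_only_is_identity():
    y = np.array([1.0, 2.0, 4.5])
    adj = adjust_phenotype(_pheno_frame(y), fixed=[])
    np.testing.assert_allclose(adj.data["y_c"], y, atol=1e-12)


def test_adjust_removes_planted_offset():
    rng = np.random.default_rng(1)
    site = np.array(["A", "B"] * 150)
    y = rng.normal(size=300) + np.where(site == "B", 3.0, 0.0)
    adj = adjust_phenotype(_pheno_frame(y, site=list(site)), fixed=["site"])
    y_c = adj.data["y_c"].to_numpy()
    assert y_c.var() < y.var()
    gap = y_c[site == "B"].mean() - y_c[site == "A"].mean()
    assert abs(gap) < 0.25  # OLS error at n=300
    assert y_c.mean() == pytest.approx(y.mean())  # location retained


def test_adjust_idempotent():
    rng = np.random.default_rng(2)
    site = list(np.array(["A", "B", "C"] * 20))
    y = rng.normal(size=60)
    once = adjust_phenotype(_pheno_frame(y, site=site), fixed=["site"])
    frame2 = _pheno_frame(once.data["y_c"].to_numpy(), site=site)
    twice = adjust_phenotype(frame2, fixed=["site"])
    np.testing.assert_allclose(twice.data["y_c"], once.data["y_c"], atol=1e-10)


def test_adjust_rank_deficient_names_aliased():
    y = np.zeros(6)
    dup = ["A", "A", "B", "B", "A", "B"]
    with pytest.raises(ValidationError, match="aliased"):
        adjust_phenotype(_pheno_frame(y, s1=dup, s2=dup), fixed=["s1", "s2"])


def test_loco_grm_contract(sim_panel):
    panel, _ = sim_panel
    loco = loco_grm_set(panel)
    assert set(loco) == set(panel.chromosomes)
    g_all = build_grm(panel)
    c = panel.chromosomes[0]
    g_c = build_grm(panel, panel.chrom_indices(c))
    g_l = loco[c]
    combined = (g_l.denominator * g_l.matrix + g_c.denominator * g_c.matrix) \
        / (g_l.denominator + g_c.denominator)
    np.testing.assert_allclose(g_all.matrix, combined, atol=1e-10)


def test_loco_single_chromosome_errors():
    panel, _ = simulate_genotypes(20, 40, n_chrom=1, seed=1)
    with pytest.raises(ParameterError):
        loco_grm_set(panel)


def test_loco_empty_pool_chromosome_falls_back(sim_panel):
    panel, _ = sim_panel
    c0 = panel.chromosomes[0]
    pool = panel.chrom_indices(c0)  # only chr c0 SNPs in the pool
    loco = loco_grm_set(panel, subset=pool)
    other = panel.chromosomes[1]
    g_pool = build_grm(panel, pool)
    np.testing.assert_allclose(loco[other].matrix, g_pool.matrix, atol=1e-12)


def test_significance_thresholds():
    sig, sug = significance_thresholds(17662)
    assert sig == pytest.approx(0.05 / 17662)
    assert sug == pytest.approx(2 * sig)
    assert significance_thresholds(1) == (0.05, 0.1)
    with pytest.raises(ParameterError):
        significance_thresholds(0)


def test_scan_reduces_to_ols_when_no_polygenic_variance(sim_panel):
    """sigma2_g = 0 makes the GLS test equal simple linear regression."""
    panel, _ = sim_panel
    rng = np.random.default_rng(5)
    y_c = rng.normal(size=panel.n_samples)
    loco = loco_grm_set(panel)
    vc = {c: (0.0, 1.0) for c in loco}
    cand = np.arange(0, panel.n_snps, 37)
    res = assoc_scan(y_c, panel, cand, loco, vc)
    for _, row in res.iterrows():
        j = int(panel.snps.index[panel.snps["snp"] == row["snp"]][0])
        d = panel.dosage[:, j].astype(float)
        x = np.column_stack([np.ones_like(d), d])
        beta = np.linalg.lstsq(x, y_c, rcond=None)[0][1]
        assert row["beta"] == pytest.approx(beta, abs=1e-8)


def test_scan_monomorphic_flagged_not_fatal(sim_panel):
    panel, _ = sim_panel
    dosage = panel.dosage.copy()
    dosage[:, 0] = 1
    panel = GenotypePanel(panel.samples, panel.snps, dosage)
    loco = loco_grm_set(panel)
    vc = {c: (0.1, 1.0) for c in loco}
    res = assoc_scan(np.zeros(panel.n_samples) + np.arange(panel.n_samples),
                     panel, np.array([0, 1]), loco, vc)
    assert bool(res.loc[res["snp"] == "rs1_0", "monomorphic"].iloc[0])
    assert not res["monomorphic"].all()


def test_scan_order_invariance(sim_panel):
    panel, _ = sim_panel
    rng = np.random.default_rng(8)
    y_c = rng.normal(size=panel.n_samples)
    loco = loco_grm_set(panel)
    vc = {c: (0.2, 0.8) for c in loco}
    cand = np.array([3, 50, 200, 400])
    a = assoc_scan(y_c, panel, cand, loco, vc).set_index("snp")
    b = assoc_scan(y_c, panel, cand[::-1], loco, vc).set_index("snp")
    pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


def test_planted_qtl_detected_permutation_destroys_signal():
    """A strong QTL clears Bonferroni; permuting y_c kills the signal."""
    panel, _ = simulate_genotypes(n=500, m=400, n_chrom=4, seed=51)
    rng = np.random.default_rng(52)
    qtl = 10
    d = panel.dosage[:, qtl].astype(float)
    y_c = 0.8 * d + rng.normal(size=500)
    loco = loco_grm_set(panel)
    vc = {c: (0.01, float(y_c.var())) for c in loco}
    cand = np.arange(0, 100)
    res = assoc_scan(y_c, panel, cand, loco, vc)
    sig, _ = significance_thresholds(cand.size)
    assert res.loc[res["snp"] == panel.snps["snp"].iloc[qtl], "p"].iloc[0] < sig
    hits = 0
    for rep in range(10):
        perm = rng.permutation(500)
        resp = assoc_scan(y_c[perm], panel, cand, loco, vc)
        if (resp["p"] < sig).any():
            hits += 1
    assert hits <= 1
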