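"""Phenotype pre-adjustment and LOCO mixed-model association scan.

Each candidate SNP is tested one at a time in the model
``y_c = mu 1 + D beta + g + e`` where the polygenic effect g has covariance
``G_loco sigma2_g`` built from every SNP except those on the candidate's
chromosome (leave one chromosome out, which avoids proximal contamination).
With variance components fixed per chromosome, beta and its standard error
come from GLS, and the p-value from a two-sided Wald test under the normal
approximation.  Genome-wide and suggestive thresholds are Bonferroni:
0.05/m and 0.1/m for m tested SNPs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .exceptions import ParameterError, ValidationError
from .grm import GRM, build_grm
from .io import MISSING, GenotypePanel, PhenotypeTable, SNPPartition
from .model import build_fixed_design
from .reml import aireml

logger = logging.getLogger(__name__)


def adjust_phenotype(pheno: PhenotypeTable, fixed: list | None = None,
                     ) -> PhenotypeTable:
    """Residualize the trait for fixed effects, keeping scale and location.

    ``y_c = y - X b_OLS + mean(y)`` fitted on rows with complete trait and
    covariates; rows with a missing covariate or trait get missing y_c.
    With an intercept-only design, ``y_c`` equals ``y`` exactly.
    """
    fixed = list(fixed) if fixed is not None else pheno.categorical + pheno.numeric
    df = pheno.data.copy()
    complete = (~df["y_missing"]) & (~df[fixed].isna().any(axis=1)
                                     if fixed else ~df["y_missing"])
    sub = df.loc[complete]
    cat = [c for c in fixed if c in pheno.categorical]
    num = [c for c in fixed if c in pheno.numeric]
    x, _ = build_fixed_design(sub, cat, num)
    y = sub[pheno.trait].to_numpy(float)
    res = sm.OLS(y, x).fit()
    y_c = np.full(len(df), np.nan)
    y_c[complete.to_numpy()] = res.resid + y.mean()
    df["y_c"] = y_c
    return PhenotypeTable(df, pheno.id_col, pheno.trait,
                          pheno.categorical, pheno.numeric)


def loco_grm_set(panel: GenotypePanel, subset: np.ndarray | None = None,
                 ) -> dict:
    """One GRM per chromosome, built from the complement SNP set.

    ``subset`` optionally restricts the GRM SNP pool (e.g. post-QC offsets).
    A chromosome that contributes no SNPs to the pool maps to the all-SNP
    GRM, with a warning.
    """
    chroms = panel.chromosomes
    if len(chroms) < 2:
        raise ParameterError("LOCO needs at least 2 chromosomes")
    pool = np.arange(panel.n_snps) if subset is None else np.asarray(subset, int)
    chrom_of = panel.snps["chrom"].to_numpy()
    out = {}
    for c in chroms:
        keep = pool[chrom_of[pool] != c]
        if keep.size == pool.size:
            logger.warning("chromosome %s has no SNPs in the GRM pool; "
                           "using the all-SNP GRM", c)
        if keep.size == 0:
            logger.warning("GRM pool has SNPs only on chromosome %s; "
                           "no LOCO GRM for it", c)
            continue
        out[c] = build_grm(panel, keep, set_name=f"loco_{c}")
    return out


def significance_thresholds(m: int) -> tuple[float, float]:
    """Bonferroni (0.05/m) and suggestive (0.1/m) p-value cutoffs."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    return 0.05 / m, 0.1 / m


def estimate_loco_varcomp(y_c: np.ndarray, loco: dict) -> dict:
    """Per-chromosome (sigma2_g, sigma2_e) for the LOCO polygenic model."""
    x = np.ones((y_c.size, 1))
    out = {}
    for c, g in loco.items():
        est = aireml(y_c, x, [g], names=["g"])
        out[c] = (est.components["g"], est.sigma2_e)
    return out


def assoc_scan(y_c: np.ndarray, panel: GenotypePanel,
               candidates: np.ndarray, loco: dict, varcomp: dict,
               ) -> pd.DataFrame:
    """GLS association test of each candidate SNP under its LOCO covariance.

    ``candidates`` are SNP map offsets; ``varcomp`` maps chromosome ->
    (sigma2_g, sigma2_e), fixed across the SNPs of that chromosome.
    Missing dosages in a candidate vector are mean-imputed; monomorphic
    candidates yield an undefined-beta row flagged ``monomorphic``.
    Output columns: snp, chr, pos, beta, se, p, neglog10p, sig, suggestive.
    """
    y_c = np.asarray(y_c, float).ravel()
    if np.isnan(y_c).any():
        raise ValidationError("y_c must be complete for tested individuals")
    candidates = np.asarray(candidates, int)
    sig_cut, sug_cut = significance_thresholds(candidates.size)
    chrom_of = panel.snps["chrom"].to_numpy()
    rows = []
    for c in pd.unique(chrom_of[candidates]):
        if c not in loco or c not in varcomp:
            raise ParameterError(f"no LOCO GRM / variance components for chr {c}")
        s2g, s2e = varcomp[c]
        v = s2g * loco[c].matrix + s2e * np.eye(y_c.size)
        lfac = np.linalg.cholesky(v)
        yw = solve_triangular(lfac, y_c, lower=True)
        onew = solve_triangular(lfac, np.ones_like(y_c), lower=True)
        for j in candidates[chrom_of[candidates] == c]:
            d = panel.dosage[:, j].astype(float)
            d[panel.dosage[:, j] == MISSING] = np.nan
            if np.all(np.isnan(d)) or np.nanstd(d) == 0:
                rows.append((panel.snps["snp"].iloc[j], c,
                             int(panel.snps["pos"].iloc[j]),
                             np.nan, np.nan, np.nan, np.nan, False, False, True))
                continue
            d = np.nan_to_num(d, nan=float(np.nanmean(d)))
            dw = solve_triangular(lfac, d, lower=True)
            xw = np.column_stack([onew, dw])
            xtx = xw.T @ xw
            coef = np.linalg.solve(xtx, xw.T @ yw)
            se = float(np.sqrt(np.linalg.inv(xtx)[1, 1]))
            beta = float(coef[1])
            zval = beta / se
            pval = float(2.0 * stats.norm.sf(abs(zval)))
            pval = max(pval, np.finfo(float).tiny)
            rows.append((panel.snps["snp"].iloc[j], c,
                         int(panel.snps["pos"].iloc[j]), beta, se, pval,
                         float(-np.log10(pval)), pval < sig_cut,
                         pval < sug_cut, False))
    out = pd.DataFrame(rows, columns=["snp", "chr", "pos", "beta", "se", "p",
                                      "neglog10p", "sig", "suggestive",
                                      "monomorphic"])
    return out


def manhattan_plot(results: pd.DataFrame, path, m: int | None = None) -> None:
    """Save a Manhattan plot of an association scan (optional helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = m or len(results)
    sig, sug = significance_thresholds(m)
    fig, ax = plt.subplots(figsize=(9, 3))
    xi = np.arange(len(results))
    for k, (_, grp) in enumerate(results.groupby("chr", sort=False)):
        ax.scatter(xi[grp.index], grp["neglog10p"], s=4,
                   color="C0" if k % 2 == 0 else "C1")
    ax.axhline(-np.log10(sig), color="green", lw=1)
    ax.axhline(-np.log10(sug), color="blue", lw=1, ls="--")
    ax.set_xlabel("marker index")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
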