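"""K-fold cross-validated prediction accuracy for the genomic models.

Accuracy is the Pearson correlation between GEBVs and corrected phenotypes
``r(GEBV, y_c)`` on each validation fold, reported as mean +/- SE over
folds.  Validation phenotypes are masked during fitting (the zero-Z-column
convention), so their GEBVs are propagated purely through the genomic
relationships.  The evenly-spaced SNP control ("evenly mined") selects the
same number of markers as the feature set at a uniform stride along the
genome map.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .blup import DesignSpec, solve_mme
from .exceptions import ParameterError, ValidationError
from .grm import GRM, build_grm, ensure_invertible
from .gwas import adjust_phenotype
from .io import GenotypePanel, PhenotypeTable, SNPPartition
from .model import build_fixed_design
from .reml import aireml

logger = logging.getLogger(__name__)

#: SNP sets entering the model, by model number.
MODEL_SETS = {1: ["all"], 2: ["exp"], 3: ["exp", "tm"]}


@dataclass
class CVResult:
    """Per-fold accuracies and their summary for one model configuration."""

    label: str
    fold_r: np.ndarray
    folds: np.ndarray          # fold label per sample
    seed: int

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.fold_r))

    @property
    def se(self) -> float:
        r = self.fold_r[~np.isnan(self.fold_r)]
        return float(np.std(r, ddof=1) / np.sqrt(r.size)) if r.size > 1 else float("nan")

    @property
    def fold_hash(self) -> str:
        return hashlib.sha256(self.folds.tobytes()).hexdigest()[:16]


def kfold_assign(samples: list, k: int, seed: int) -> np.ndarray:
    """Random fold label (0..k-1) per sample; fold sizes differ by <= 1."""
    n = len(samples)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError("k larger than sample count")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


def evenly_spaced_subset(panel: GenotypePanel, count: int, seed: int = 0,
                         ) -> SNPPartition:
    """Evenly-spaced control set: every floor(M/count)-th SNP in map order.

    The starting offset within the first stride is seed-chosen; exactly
    ``count`` SNPs are returned, partitioned against their complement.
    """
    m = panel.n_snps
    if count < 1:
        raise ParameterError("count must be >= 1")
    if count > m:
        raise ParameterError("count exceeds SNP count")
    stride = m // count
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, max(stride, 1)))
    idx = offset + stride * np.arange(count)
    return SNPPartition(m, em=idx)


def _fold_fit_gls(y_train: np.ndarray, x_train: np.ndarray, grms: list,
                  theta: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """GEBVs for all individuals from a training-records GLS-BLUP fit.

    Identical to solving the zero-Z-column MME (the package's central
    equivalence property); factorizes the n_train x n_train V instead.
    """
    v = theta[-1] * np.eye(train_idx.size)
    for s2, g in zip(theta[:-1], grms):
        v += s2 * g.matrix[np.ix_(train_idx, train_idx)]
    fac = cho_factor(v, lower=True)
    vix = cho_solve(fac, x_train)
    viy = cho_solve(fac, y_train)
    beta = np.linalg.solve(x_train.T @ vix, x_train.T @ viy)
    r = cho_solve(fac, y_train - x_train @ beta)
    gebv = np.zeros(grms[0].n)
    for s2, g in zip(theta[:-1], grms):
        gebv += s2 * (g.matrix[:, train_idx] @ r)
    return gebv


def cv_accuracy(panel: GenotypePanel, pheno: PhenotypeTable,
                partition: SNPPartition, model: int,
                varcomp_policy: str = "per_fold", k: int = 10, seed: int = 0,
                set_names: list | None = None, label: str | None = None,
                fixed: list | None = None, solver: str = "gls",
                grms: dict | None = None) -> CVResult:
    """K-fold CV accuracy of one genomic model configuration.

    ``varcomp_policy`` is ``"per_fold"`` (re-estimate on each training fold;
    default, avoids leakage) or ``"global"`` (estimate once on all data and
    share across folds).  ``set_names`` overrides the SNP sets implied by
    ``model`` (e.g. ``["exp_em", "em"]`` for the evenly-spaced control).
    ``solver="mme"`` routes each fold through the explicit zero-Z-column
    mixed-model equations instead of the equivalent GLS factorization.
    Pre-built GRMs can be passed via ``grms`` (name -> GRM) to share work
    across configurations.
    """
    if varcomp_policy not in ("per_fold", "global"):
        raise ParameterError("varcomp_policy must be 'per_fold' or 'global'")
    names = set_names or MODEL_SETS[model]
    if any(n not in partition for n in names):
        raise ParameterError(f"partition lacks sets {names}")
    # Blend once if singular so the GLS and MME fold routes share one G.
    glist = [ensure_invertible(grms[n] if grms and n in grms
                               else build_grm(panel, partition.indices(n),
                                              set_name=n))
             for n in names]

    pheno = pheno if "y_c" in pheno.data.columns else adjust_phenotype(pheno, fixed)
    df = pheno.data
    order = {s: i for i, s in enumerate(df[pheno.id_col])}
    df = df.iloc[[order[s] for s in panel.samples]].reset_index(drop=True)
    y = df[pheno.trait].to_numpy(float)
    y_c = df["y_c"].to_numpy(float)
    fixed = list(fixed) if fixed is not None else pheno.categorical + pheno.numeric
    cat = [c for c in fixed if c in pheno.categorical]
    num = [c for c in fixed if c in pheno.numeric]
    x, _ = build_fixed_design(df, cat, num)

    folds = kfold_assign(panel.samples, k, seed)
    theta_global = None
    if varcomp_policy == "global":
        est = aireml(y, x, glist)
        theta_global = np.array(list(est.components.values()) + [est.sigma2_e])

    fold_r = np.full(k, np.nan)
    for f in range(k):
        train = np.flatnonzero(folds != f)
        val = np.flatnonzero(folds == f)
        if theta_global is None:
            est = aireml(y[train], x[train], [
                GRM(list(np.array(panel.samples)[train]),
                    g.matrix[np.ix_(train, train)], g.denominator,
                    set_name=g.set_name, n_snps=g.n_snps) for g in glist])
            theta = np.array(list(est.components.values()) + [est.sigma2_e])
        else:
            theta = theta_global
        theta = np.maximum(theta, 1e-10 * max(float(np.var(y)), 1e-30))
        if solver == "mme":
            design = DesignSpec.from_training(x, train, len(panel.samples))
            comps = [(g, theta[-1] / theta[i]) for i, g in enumerate(glist)]
            gebv = solve_mme(y[train], design, comps,
                             sample_ids=panel.samples).gebv
        else:
            gebv = _fold_fit_gls(y[train], x[train], glist, theta, train)
        yv = y_c[val]
        if np.nanstd(yv) == 0 or np.std(gebv[val]) == 0:
            logger.warning("fold %d has zero variance; r undefined", f)
            continue
        fold_r[f] = float(np.corrcoef(gebv[val], yv)[0, 1])
    return CVResult(label or "+".join(names), fold_r, folds, seed)


def compare_models(panel: GenotypePanel, pheno: PhenotypeTable,
                   partition: SNPPartition, k: int = 10, seed: int = 0,
                   varcomp_policy: str = "per_fold", fixed: list | None = None,
                   em_seed: int | None = None) -> pd.DataFrame:
    """Run the four standard configurations on identical folds.

    Configurations: one GRM on all SNPs (Im), one GRM on the feature
    complement (exp), two GRMs feature + complement (exp+tm), and the
    evenly-spaced control pair (exp+em).  Returns a tidy table of mean
    accuracy and SE per configuration; per-fold detail in ``attrs``.
    """
    if "tm" not in partition or partition.indices("tm").size == 0:
        raise ParameterError("compare_models needs a non-empty tm set")
    em_part = evenly_spaced_subset(panel, partition.indices("tm").size,
                                   seed if em_seed is None else em_seed)
    part_em = SNPPartition(panel.n_snps, tm=partition.indices("tm"),
                           em=em_part.indices("em"))
    pheno = pheno if "y_c" in pheno.data.columns else adjust_phenotype(pheno, fixed)
    configs = [
        ("Im", partition, 1, None),
        ("exp", partition, 2, None),
        ("exp+tm", partition, 3, None),
        ("exp+em", part_em, 3, ["exp_em", "em"]),
    ]
    results = []
    for lbl, part, model, sets in configs:
        results.append(cv_accuracy(panel, pheno, part, model,
                                   varcomp_policy=varcomp_policy, k=k,
                                   seed=seed, set_names=sets, label=lbl,
                                   fixed=fixed))
    hashes = {r.fold_hash for r in results}
    if len(hashes) != 1:  # same seed must give identical folds
        raise ValidationError("fold assignments differ across configurations")
    table = pd.DataFrame({
        "model": [r.label for r in results],
        "mean_r": [r.mean_r for r in results],
        "se": [r.se for r in results],
    })
    table.attrs["cv_results"] = results
    return table
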