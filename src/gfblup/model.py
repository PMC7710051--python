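"""Model/Results front end over AI-REML variance components and GBLUP.

``GenomicMixedModel`` holds the phenotype vector, the fixed-effect design
and one or two genomic relationship matrices; ``fit()`` runs AI-REML for the
variance components and then solves the mixed-model equations at the
estimated shrinkage values, returning a ``GenomicMixedModelResults`` with
estimates, standard errors, heritability, GEBVs and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blup import DesignSpec, MMEFit, solve_mme
from .exceptions import ParameterError, ValidationError
from .grm import GRM
from .io import PhenotypeTable
from .reml import VarianceEstimate, aireml, heritability


def build_fixed_design(df: pd.DataFrame, categorical: list, numeric: list,
                       ) -> tuple[np.ndarray, list]:
    """Intercept + treatment-coded categoricals (first level reference) + numerics.

    Returns the design matrix and its column names.  Raises when the matrix
    is rank deficient, naming the aliased columns.
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in categorical:
        levels = sorted(df[c].dropna().unique())
        for lev in levels[1:]:
            cols.append((df[c] == lev).to_numpy(float))
            names.append(f"{c}[{lev}]")
    for c in numeric:
        cols.append(df[c].to_numpy(float))
        names.append(c)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        aliased = []
        r = 0
        kept: list[int] = []
        for j in range(x.shape[1]):
            if np.linalg.matrix_rank(x[:, kept + [j]]) > r:
                kept.append(j)
                r += 1
            else:
                aliased.append(names[j])
        raise ValidationError(f"fixed-effect design rank deficient; aliased: {aliased}")
    return x, names


class GenomicMixedModel:
    """Mixed model ``y = Xb + sum_k g_k + e`` with genomic covariances G_k.

    Parameters
    ----------
    y : array
        Phenotype records, one per individual in the GRMs (complete records).
    x : array
        Fixed-effect design, including the intercept.
    grms : list of GRM
        One (models 1-2) or two (model 3) genomic relationship matrices over
        the same individuals in the same order.
    """

    def __init__(self, y, x, grms, sample_ids=None):
        self.y = np.asarray(y, float).ravel()
        self.x = np.atleast_2d(np.asarray(x, float))
        if self.x.shape[0] != self.y.size:
            self.x = self.x.T
        self.grms = list(grms) if isinstance(grms, (list, tuple)) else [grms]
        if not 1 <= len(self.grms) <= 2:
            raise ParameterError("1 or 2 genomic components supported")
        n = self.y.size
        for g in self.grms:
            if g.n != n:
                raise ValidationError("GRM dimension does not match y")
        self.sample_ids = list(sample_ids) if sample_ids else self.grms[0].sample_ids
        self.exog_names = [f"x{j}" for j in range(self.x.shape[1])]

    @classmethod
    def from_dataframe(cls, pheno: PhenotypeTable, grms,
                       categorical: list | None = None,
                       numeric: list | None = None) -> "GenomicMixedModel":
        """Build from a PhenotypeTable, aligning rows to the GRM sample order."""
        grms = list(grms) if isinstance(grms, (list, tuple)) else [grms]
        df = pheno.data
        order = {s: i for i, s in enumerate(df[pheno.id_col])}
        missing = [s for s in grms[0].sample_ids if s not in order]
        if missing:
            raise ValidationError(f"GRM ids without phenotype rows: {missing[:5]}")
        df = df.iloc[[order[s] for s in grms[0].sample_ids]].reset_index(drop=True)
        cat = pheno.categorical if categorical is None else categorical
        num = pheno.numeric if numeric is None else numeric
        x, names = build_fixed_design(df, cat, num)
        mdl = cls(df[pheno.trait].to_numpy(float), x, grms,
                  sample_ids=grms[0].sample_ids)
        mdl.exog_names = names
        return mdl

    def fit(self, init=None, tol: float = 1e-8, max_iter: int = 200,
            ) -> "GenomicMixedModelResults":
        """Estimate variance components by AI-REML, then solve the MME."""
        est = aireml(self.y, self.x, self.grms, init=init, tol=tol,
                     max_iter=max_iter)
        lambdas = est.lambdas()
        design = DesignSpec.from_training(self.x, np.arange(self.y.size),
                                          len(self.sample_ids))
        comps = [(g, lambdas[name]) for g, name in zip(self.grms, est.names)]
        mme = solve_mme(self.y, design, comps, sample_ids=self.sample_ids)
        return GenomicMixedModelResults(self, est, mme)


class GenomicMixedModelResults:
    """Variance components, heritability and GEBVs from a fitted model."""

    def __init__(self, model: GenomicMixedModel, varcomp: VarianceEstimate,
                 mme: MMEFit):
        self.model = model
        self.varcomp = varcomp
        self.mme = mme
        self.converged = varcomp.converged
        self.loglik = varcomp.loglik

    @property
    def params(self) -> pd.Series:
        d = dict(self.varcomp.components)
        d["e"] = self.varcomp.sigma2_e
        return pd.Series(d, name="sigma2")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.varcomp.se, name="se")

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self.mme.beta, index=self.model.exog_names, name="beta")

    @property
    def gebv(self) -> pd.DataFrame:
        return self.mme.gebv_frame()

    @property
    def h2(self) -> float:
        model_no = 3 if len(self.varcomp.components) == 2 else 1
        return heritability(self.varcomp, model_no)

    def summary(self) -> str:
        lines = ["Genomic mixed model (AI-REML + GBLUP)",
                 "=" * 46,
                 f"n individuals:      {len(self.model.sample_ids)}",
                 f"genomic components: {', '.join(self.varcomp.names)}",
                 f"REML log-likelihood: {self.loglik:.4f}"
                 f"   iterations: {self.varcomp.n_iter}"
                 f"   converged: {self.converged}",
                 "-" * 46,
                 f"{'component':<14}{'sigma2':>12}{'SE':>12}"]
        for name in self.varcomp.names + ["e"]:
            v = (self.varcomp.components.get(name)
                 if name != "e" else self.varcomp.sigma2_e)
            s = self.varcomp.se.get(name, float("nan"))
            lines.append(f"{name:<14}{v:>12.4f}{s:>12.4f}")
        lines.append("-" * 46)
        lines.append(f"h2 = {self.h2:.4f}  (rounded: "
                     f"{heritability(self.varcomp, 3 if len(self.varcomp.components) == 2 else 1, rounded=True):.2f})")
        lines.append(f"lambda: " + ", ".join(
            f"{k}={v:.4g}" for k, v in self.varcomp.lambdas().items()))
        return "\n".join(lines)
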