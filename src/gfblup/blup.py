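"""Mixed-model-equation GBLUP solvers and a brute-force GLS oracle.

For one genomic component the mixed-model equations are

    [ X'X        X'Z      ] [b]   [X'y]
    [ Z'X  Z'Z + lambda G^-1 ] [u] = [Z'y],    lambda = sigma2_E / sigma2_g,

and for two components the analogous three-block system with
``Z'Z + lambda_k G_k^-1`` on the diagonal blocks.  Individuals without a
phenotype enter through all-zero Z columns; their GEBVs are propagated
through G by the equations themselves.  The combined GEBV under the
two-component model is the sum of the per-component solutions.

The GLS route (``gls_blup_oracle``) computes the same quantities from
``V = sum_k Z G_k Z' sigma2_k + I sigma2_E`` by direct dense inversion and
serves as the independent correctness oracle for the MME solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .exceptions import LinAlgError, ParameterError, ValidationError
from .grm import GRM, grm_inverse


@dataclass
class DesignSpec:
    """Fixed-effect incidence X and record-to-individual incidence Z."""

    x: np.ndarray  # (records, p)
    z: np.ndarray  # (records, individuals in G); each row has exactly one 1

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, float))
        self.z = np.atleast_2d(np.asarray(self.z, float))
        if self.x.shape[0] != self.z.shape[0]:
            raise ValidationError("X and Z row counts differ")
        row_sums = self.z.sum(axis=1)
        if not np.all((row_sums == 1) & (self.z.max(axis=1) == 1)):
            raise ValidationError("each Z row must have exactly one 1")

    @classmethod
    def from_training(cls, x_full: np.ndarray, train_idx: np.ndarray,
                      n_individuals: int) -> "DesignSpec":
        """Design for records = training individuals, zero Z columns elsewhere."""
        train_idx = np.asarray(train_idx, int)
        z = np.zeros((train_idx.size, n_individuals))
        z[np.arange(train_idx.size), train_idx] = 1.0
        return cls(np.atleast_2d(x_full)[train_idx], z)


@dataclass
class MMEFit:
    """Solutions of the mixed-model equations."""

    beta: np.ndarray          # fixed-effect solutions
    u: dict                   # component name -> GEBV vector over individuals
    gebv: np.ndarray          # combined GEBV (sum over components)
    lambdas: dict             # component name -> lambda used
    sample_ids: list | None = None
    residual_norm: float = 0.0

    def gebv_frame(self) -> pd.DataFrame:
        ids = self.sample_ids or list(range(self.gebv.size))
        out = pd.DataFrame({"id": ids})
        for name, vec in self.u.items():
            out[f"u_{name}"] = vec
        out["gebv"] = self.gebv
        return out


def _component_names(components: list) -> list:
    names = []
    for k, (g, _) in enumerate(components):
        name = getattr(g, "set_name", "") or f"g{k + 1}"
        while name in names:
            name += f"_{k + 1}"
        names.append(name)
    return names


def solve_mme(y: np.ndarray, design: DesignSpec, components: list,
              sample_ids: list | None = None) -> MMEFit:
    """Solve the 1- or 2-component mixed-model equations.

    ``components`` is a list of ``(GRM, lambda)`` pairs (max 2).  Solved via
    a Cholesky factorization of the symmetric coefficient matrix; the
    solution is checked against the normal equations to a residual norm
    below ``1e-8 * ||RHS||``.
    """
    if not 1 <= len(components) <= 2:
        raise ParameterError("solve_mme supports 1 or 2 genomic components")
    for _, lam in components:
        if lam <= 0:
            raise ParameterError("lambda must be positive")
    y = np.asarray(y, float).ravel()
    x, z = design.x, design.z
    if y.size != x.shape[0]:
        raise ValidationError("y length does not match design rows")
    n_ind = z.shape[1]
    p = x.shape[1]

    xtx = x.T @ x
    xtz = x.T @ z
    ztz = z.T @ z
    c_dim = p + len(components) * n_ind
    c = np.zeros((c_dim, c_dim))
    rhs = np.zeros(c_dim)
    c[:p, :p] = xtx
    rhs[:p] = x.T @ y
    zty = z.T @ y
    ginvs = []
    for k, (g, lam) in enumerate(components):
        ginvs.append(grm_inverse(g))
        a = p + k * n_ind
        c[:p, a:a + n_ind] = xtz
        c[a:a + n_ind, :p] = xtz.T
        rhs[a:a + n_ind] = zty
        for l in range(len(components)):
            b = p + l * n_ind
            c[a:a + n_ind, b:b + n_ind] = ztz
        c[a:a + n_ind, a:a + n_ind] = ztz + lam * ginvs[k]

    try:
        fac = cho_factor(c, lower=True)
        sol = cho_solve(fac, rhs)
    except np.linalg.LinAlgError as err:
        blocks = "fixed-effect (X'X)" if p and np.linalg.matrix_rank(xtx) < p \
            else "random-effect (Z'Z + lambda G^-1)"
        raise LinAlgError(f"singular MME coefficient matrix in {blocks} block") from err
    rhs_norm = float(np.linalg.norm(rhs))
    res = float(np.linalg.norm(c @ sol - rhs))
    for _ in range(5):  # iterative refinement for ill-conditioned G^-1 blocks
        if res <= 1e-8 * max(rhs_norm, 1.0):
            break
        sol = sol + cho_solve(fac, rhs - c @ sol)
        res = float(np.linalg.norm(c @ sol - rhs))
    if res > 1e-8 * max(rhs_norm, 1.0):
        raise LinAlgError(f"MME solution residual {res:.3e} too large")

    beta = sol[:p]
    u = {}
    names = _component_names(components)
    for k, name in enumerate(names):
        a = p + k * n_ind
        u[name] = sol[a:a + n_ind]
    gebv = np.sum(list(u.values()), axis=0)
    lambdas = {name: lam for name, (_, lam) in zip(u, components)}
    ids = sample_ids or components[0][0].sample_ids
    return MMEFit(beta, u, gebv, lambdas, sample_ids=ids, residual_norm=res)


def gls_blup_oracle(y: np.ndarray, design: DesignSpec, components: list,
                    sigma2_e: float, sample_ids: list | None = None) -> MMEFit:
    """BLUP via direct GLS: the independent dense-V oracle (small n only).

    ``components`` is a list of ``(GRM, sigma2_k)``.  Computes
    ``V = sum_k Z G_k Z' sigma2_k + I sigma2_E``, then
    ``b = (X'V^-1X)^-1 X'V^-1 y`` and ``u_k = sigma2_k G_k Z' V^-1 (y - Xb)``.
    """
    if sigma2_e <= 0:
        raise ParameterError("sigma2_e must be positive")
    y = np.asarray(y, float).ravel()
    x, z = design.x, design.z
    n_rec = y.size
    v = sigma2_e * np.eye(n_rec)
    for g, s2 in components:
        v += s2 * (z @ g.matrix @ z.T)
    try:
        fac = cho_factor(v, lower=True)
    except np.linalg.LinAlgError as err:
        raise LinAlgError("V not positive definite") from err
    viy = cho_solve(fac, y)
    vix = cho_solve(fac, x)
    beta = np.linalg.solve(x.T @ vix, x.T @ viy)
    r = cho_solve(fac, y - x @ beta)
    u = {}
    for name, (g, s2) in zip(_component_names(components), components):
        u[name] = s2 * (g.matrix @ (z.T @ r))
    gebv = np.sum(list(u.values()), axis=0)
    lambdas = {name: sigma2_e / s2 for name, (_, s2) in zip(u, components)}
    ids = sample_ids or components[0][0].sample_ids
    return MMEFit(beta, u, gebv, lambdas, sample_ids=ids)


def predict_validation(fit: MMEFit, validation_ids: list) -> np.ndarray:
    """GEBVs of validation individuals (already propagated through G)."""
    if fit.sample_ids is None:
        raise ValidationError("fit carries no sample ids")
    lookup = {s: i for i, s in enumerate(fit.sample_ids)}
    missing = [v for v in validation_ids if v not in lookup]
    if missing:
        raise ValidationError(f"ids not in G: {missing[:5]}")
    return fit.gebv[[lookup[v] for v in validation_ids]]
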