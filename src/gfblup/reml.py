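"""REML log-likelihood and AI-REML for one or two genomic components.

The model is ``y = X b + sum_k g_k + e`` with ``g_k ~ N(0, G_k sigma2_k)``
and ``e ~ N(0, I sigma2_E)``, so ``V = sum_k sigma2_k G_k + sigma2_E I``.
The restricted log-likelihood (up to a constant) is

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P   = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

AI-REML takes Newton-type steps using the average-information matrix
``AI_kl = 1/2 (Py)' G_k P G_l (Py)``; when a step proposes a negative
component or decreases the likelihood it is halved, and if that fails an
EM-style multiplicative update is used instead, so accepted iterations never
decrease ``l_R``.  Components that collapse are pinned to a small floor and
the convergence flag is honest.

Heritability follows the three single/two-component formulas:
model 1: s2_all/(s2_all+s2_E); model 2: s2_mt/(s2_mt+s2_E);
model 3: (s2_t+s2_mt)/(s2_t+s2_mt+s2_E).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import LinAlgError, ParameterError

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.405 -> 0.41, -0.405 -> -0.41)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VarianceEstimate:
    """Variance components, their AI standard errors and the fit record."""

    components: dict                 # name -> sigma2 (trait units squared)
    sigma2_e: float
    loglik: float
    n_iter: int
    converged: bool
    se: dict = field(default_factory=dict)   # name (incl. 'e') -> approx SE
    history: list = field(default_factory=list)  # per-iteration loglik

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()) or self.sigma2_e < 0:
            raise ParameterError("variance components must be non-negative")

    @property
    def names(self) -> list:
        return list(self.components)

    def lambdas(self) -> dict:
        """Shrinkage lambda_k = sigma2_E / sigma2_k per genomic component."""
        return {k: self.sigma2_e / v for k, v in self.components.items()}


def heritability(est: VarianceEstimate, model: int, rounded: bool = False) -> float:
    """Heritability under the one- or two-component model formulas.

    model 1 uses the single all-SNP component; model 2 the single
    complement-panel component; model 3 the sum of the two components.
    ``rounded`` applies the 2-decimal half-away-from-zero presentation.
    """
    comps = list(est.components.values())
    if model in (1, 2):
        if len(comps) != 1:
            raise ParameterError(f"model {model} needs exactly 1 genomic component")
        num = comps[0]
    elif model == 3:
        if len(comps) != 2:
            raise ParameterError("model 3 needs exactly 2 genomic components")
        num = comps[0] + comps[1]
    else:
        raise ParameterError("model must be 1, 2 or 3")
    h2 = num / (num + est.sigma2_e) if (num + est.sigma2_e) > 0 else 0.0
    return round_half_away(h2, 2) if rounded else h2


def _reml_pieces(y: np.ndarray, x: np.ndarray, gs: list, theta: np.ndarray):
    """Return (loglik, P, Py) for variance vector theta = (sigma2_k..., sigma2_E)."""
    n = y.size
    v = theta[-1] * np.eye(n)
    for s2, g in zip(theta[:-1], gs):
        v += s2 * g
    try:
        cv = cho_factor(v, lower=True)
    except np.linalg.LinAlgError as err:
        raise LinAlgError(f"V not positive definite at theta={theta}") from err
    logdet_v = 2.0 * np.log(np.diag(cv[0])).sum()
    vinv = cho_solve(cv, np.eye(n))
    xtvx = x.T @ vinv @ x
    try:
        cx = cho_factor(xtvx, lower=True)
    except np.linalg.LinAlgError as err:
        raise LinAlgError("X'V^-1X singular; X not full rank?") from err
    logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
    vinv_x = vinv @ x
    p = vinv - vinv_x @ cho_solve(cx, vinv_x.T)
    py = p @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
    return ll, p, py


def reml_loglik(y: np.ndarray, x: np.ndarray, gs: list,
                params: np.ndarray) -> float:
    """Restricted log-likelihood at ``params = (sigma2_1[, sigma2_2], sigma2_E)``.

    ``gs`` is the list of genomic covariance matrices (GRM ``.matrix`` or
    plain arrays); the residual identity component is implicit and last in
    ``params``.  Up to the model-free constant.
    """
    y = np.asarray(y, float).ravel()
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != y.size:
        x = x.T
    mats = [g.matrix if hasattr(g, "matrix") else np.asarray(g, float) for g in gs]
    ll, _, _ = _reml_pieces(y, x, mats, np.asarray(params, float))
    return ll


def aireml(y: np.ndarray, x: np.ndarray, gs: list, names: list | None = None,
           init: np.ndarray | None = None, tol: float = 1e-8,
           tol_param: float = 1e-6, max_iter: int = 200) -> VarianceEstimate:
    """AI-REML with step-halving and EM fallback; 1 or 2 genomic components.

    Initialisation (when ``init`` is None): the residual takes half the
    phenotypic variance of y after fixed-effect projection, the genomic
    components split the other half equally.  Components collapsing toward
    zero are pinned at a floor of ``1e-8 * var(y)``.  Hitting ``max_iter``
    returns the best estimate found with ``converged=False``.
    """
    y = np.asarray(y, float).ravel()
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != y.size:
        x = x.T
    mats = [g.matrix if hasattr(g, "matrix") else np.asarray(g, float) for g in gs]
    n_g = len(mats)
    if not 1 <= n_g <= 2:
        raise ParameterError("aireml supports 1 or 2 genomic components")
    if names is None:
        names = [getattr(g, "set_name", f"g{k+1}") for k, g in enumerate(gs)]

    # Fixed-effect projection for a scale-free start.
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    var_y = float(resid @ resid) / max(y.size - x.shape[1], 1)
    floor = 1e-8 * max(var_y, np.finfo(float).tiny)
    if init is None:
        theta = np.array([0.5 * var_y / n_g] * n_g + [0.5 * var_y])
    else:
        theta = np.maximum(np.asarray(init, float), floor)

    mats_all = mats + [np.eye(y.size)]
    ll, p, py = _reml_pieces(y, x, mats, theta)
    history = [ll]
    best_theta, best_ll = theta.copy(), ll
    converged = False
    ai = None
    it = 0
    for it in range(1, max_iter + 1):
        # Score and average information over all components incl. residual.
        q = [m @ py for m in mats_all]
        score = np.array([-0.5 * (np.sum(p * m) - py @ qk)
                          for m, qk in zip(mats_all, q)])
        ai = 0.5 * np.array([[qi @ p @ qj for qj in q] for qi in q])
        at_floor = theta <= floor * (1 + 1e-12)
        free = ~(at_floor & (score < 0))
        delta = np.zeros_like(theta)
        try:
            delta[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            delta[free] = score[free] / np.maximum(np.diag(ai)[free], 1e-12)

        accepted = False
        step = 1.0
        for _ in range(12):
            prop = np.maximum(theta + step * delta, floor)
            try:
                ll_new, p_new, py_new = _reml_pieces(y, x, mats, prop)
            except LinAlgError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM-style multiplicative fallback: fixed point of the score.
            prop = theta.copy()
            for k, (m, qk) in enumerate(zip(mats_all, q)):
                tr = np.sum(p * m)
                if tr > 0 and theta[k] > floor:
                    prop[k] = theta[k] * float(py @ qk) / tr
            prop = np.maximum(prop, floor)
            try:
                ll_new, p_new, py_new = _reml_pieces(y, x, mats, prop)
            except LinAlgError:
                break
            if ll_new < ll - 1e-10:
                break  # no ascent direction left; stop at best seen

        rel_change = np.max(np.abs(prop - theta) / np.maximum(np.abs(theta), floor))
        theta, ll, p, py = prop, ll_new, p_new, py_new
        history.append(ll)
        if ll > best_ll:
            best_ll, best_theta = ll, theta.copy()
        if abs(history[-1] - history[-2]) < tol or rel_change < tol_param:
            converged = True
            break

    theta = best_theta
    se = {}
    if ai is not None:
        try:
            ai_inv = np.linalg.inv(ai)
            errs = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
            se = {name: float(s) for name, s in zip(names + ["e"], errs)}
        except np.linalg.LinAlgError:
            se = {}
    components = {name: float(v) for name, v in zip(names, theta[:-1])}
    return VarianceEstimate(components, float(theta[-1]), float(best_ll),
                            n_iter=it, converged=converged, se=se,
                            history=history)
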