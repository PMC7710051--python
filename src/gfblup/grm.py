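"""SNP quality control and VanRaden genomic relationship matrices.

The GRM over a SNP subset S is ``G = M M' / (2 * sum_j p_j (1 - p_j))``
with M the dosage matrix column-centered by twice the sample allele
frequency ``p_j``.  Missing dosages are mean-imputed (centered zero), the
standard treatment, which preserves the zero-row-sum identity when the
frequencies are sample-estimated.  Numerators and denominators are additive
over disjoint SNP sets, so a GRM built on a union equals the
denominator-weighted combination of the parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import LinAlgError, ParameterError, ValidationError
from .io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Symmetric relationship matrix with its VanRaden denominator."""

    sample_ids: list
    matrix: np.ndarray
    denominator: float
    set_name: str = "all"
    n_snps: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValidationError("GRM shape does not match sample ids")
        if not np.isfinite(self.matrix).all():
            raise ValidationError("GRM has non-finite entries")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-10:
            raise ValidationError("GRM is not symmetric within 1e-10")
        if self.denominator <= 0:
            raise ValidationError("GRM denominator must be positive")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class QCReport:
    """Bookkeeping of SNPs removed by each quality-control filter."""

    n_input: int
    removed_maf: int
    removed_missing: int
    removed_total: int
    retained: int

    def __post_init__(self) -> None:
        if self.removed_total + self.retained != self.n_input:
            raise ValidationError("QC report does not reconcile")


def allele_freqs(panel: GenotypePanel, subset: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sample allele-1 frequencies ``p_j`` over a SNP subset.

    ``p_j`` = (sum of non-missing dosages) / (2 x non-missing count).
    Returns ``(p, all_missing)``; SNPs with no calls get ``p = nan`` and are
    flagged in the boolean ``all_missing`` vector.
    """
    idx = np.arange(panel.n_snps) if subset is None else np.asarray(subset, int)
    if idx.size == 0:
        raise ParameterError("SNP subset is empty")
    dos = panel.dosage[:, idx]
    obs = dos != MISSING
    counts = obs.sum(axis=0)
    sums = np.where(obs, dos, 0).sum(axis=0)
    all_missing = counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(all_missing, np.nan, sums / (2.0 * np.maximum(counts, 1)))
    if all_missing.any():
        logger.warning("%d SNPs have no non-missing calls", all_missing.sum())
    return p, all_missing


def apply_snp_qc(panel: GenotypePanel, maf_min: float = 0.0,
                 max_missing: float = 1.0) -> tuple[GenotypePanel, QCReport]:
    """Remove SNPs failing MAF or missing-call-rate filters, order preserved.

    A SNP fails if ``min(p, 1-p) < maf_min`` or its missing fraction exceeds
    ``max_missing`` (the PLINK ``--geno`` convention).  SNPs with no calls
    at all fail the missingness filter.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ParameterError("maf_min must be in [0, 0.5)")
    if not 0.0 <= max_missing <= 1.0:
        raise ParameterError("max_missing must be in [0, 1]")
    p, all_missing = allele_freqs(panel)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    miss_frac = (panel.dosage == MISSING).mean(axis=0)
    fail_maf = ~all_missing & (maf < maf_min)
    fail_miss = (miss_frac > max_missing) | all_missing
    keep = ~(fail_maf | fail_miss)
    if not keep.any():
        raise ValidationError("QC removed every SNP")
    report = QCReport(
        n_input=panel.n_snps,
        removed_maf=int(fail_maf.sum()),
        removed_missing=int(fail_miss.sum()),
        removed_total=int((~keep).sum()),
        retained=int(keep.sum()),
    )
    return panel.snp_subset(np.flatnonzero(keep)), report


def build_grm(panel: GenotypePanel, subset: np.ndarray | None = None,
              set_name: str = "all") -> GRM:
    """VanRaden GRM over a SNP subset with sample-estimated frequencies.

    Monomorphic SNPs contribute zero to both numerator and denominator;
    missing dosages are set to the column mean (centered zero) before the
    cross-product.
    """
    idx = np.arange(panel.n_snps) if subset is None else np.asarray(subset, int)
    p, all_missing = allele_freqs(panel, idx)
    p = np.where(all_missing, 0.0, p)  # no calls: centered column is all zero
    het = 2.0 * p * (1.0 - p)
    denom = float(het.sum())
    if denom <= 0:
        raise LinAlgError("all SNPs in the subset are monomorphic (denominator 0)")
    dos = panel.dosage[:, idx].astype(float)
    dos[panel.dosage[:, idx] == MISSING] = np.nan
    m_mat = np.nan_to_num(dos - 2.0 * p)
    g = (m_mat @ m_mat.T) / denom
    return GRM(panel.samples, g, denom, set_name=set_name, n_snps=idx.size)


def regularize_grm(g: GRM, blend_weight: float = 0.95, ridge: float = 0.0) -> GRM:
    """Return ``alpha*G + (1-alpha)*I + ridge*I``; identity when alpha=1, ridge=0.

    Raises with a smallest-eigenvalue diagnostic if the result is still
    numerically singular.
    """
    if not 0.0 < blend_weight <= 1.0:
        raise ParameterError("blend_weight must be in (0, 1]")
    if ridge < 0.0:
        raise ParameterError("ridge must be non-negative")
    if blend_weight == 1.0 and ridge == 0.0:
        return g
    mat = blend_weight * g.matrix + (1.0 - blend_weight + ridge) * np.eye(g.n)
    smallest = float(np.linalg.eigvalsh(mat)[0])
    if smallest <= 1e-12 * max(1.0, float(np.trace(mat)) / g.n):
        raise LinAlgError(
            f"regularized GRM still singular (smallest eigenvalue {smallest:.3e})"
        )
    return GRM(g.sample_ids, mat, g.denominator, set_name=g.set_name,
               n_snps=g.n_snps)


def grm_inverse(g: GRM, auto_regularize: bool = True) -> np.ndarray:
    """Inverse of the GRM, blending toward identity only if inversion fails.

    A GRM with sample-estimated frequencies is singular by construction
    (rows sum to zero), so failure is detected both as a Cholesky breakdown
    and as a numerically inaccurate inverse.
    """
    from scipy.linalg import cho_factor, cho_solve

    try:
        c = cho_factor(g.matrix)
        inv = cho_solve(c, np.eye(g.n))
        # Accuracy probe: worthless inverses pass Cholesky when the matrix is
        # numerically PSD but rank deficient.
        probe = np.abs(g.matrix @ inv[:, 0] - np.eye(g.n)[:, 0]).max()
        if probe < 1e-6:
            return inv
    except np.linalg.LinAlgError:
        pass
    if not auto_regularize:
        raise LinAlgError(f"GRM {g.set_name!r} is singular")
    logger.info("GRM %r singular; blending 0.95 G + 0.05 I for inversion",
                g.set_name)
    reg = regularize_grm(g, blend_weight=0.95, ridge=0.0)
    c = cho_factor(reg.matrix)
    return cho_solve(c, np.eye(g.n))


def ensure_invertible(g: GRM, blend_weight: float = 0.95) -> GRM:
    """Return ``g`` if numerically invertible, else the 0.95-blended version.

    Used where one G matrix must serve both a factorized-V route and an
    explicit G^-1 route so the two see the same model.
    """
    from scipy.linalg import cho_factor, cho_solve

    try:
        c = cho_factor(g.matrix)
        probe = np.abs(g.matrix @ cho_solve(c, np.eye(g.n)[:, 0])
                       - np.eye(g.n)[:, 0]).max()
        if probe < 1e-6:
            return g
    except np.linalg.LinAlgError:
        pass
    return regularize_grm(g, blend_weight=blend_weight)


def write_grm(g: GRM, prefix) -> None:
    """Persist as GCTA-style text: ``<prefix>.grm.id`` + lower-triangle triplets."""
    prefix = Path(prefix)
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in g.sample_ids:
            fh.write(f"{s}\t{s}\n")
    with open(f"{prefix}.grm", "w") as fh:
        for i in range(g.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{g.n_snps}\t{g.matrix[i, j]:.10g}\n")


def read_grm(prefix) -> GRM:
    """Read the GCTA-style text layout written by :func:`write_grm`."""
    prefix = Path(prefix)
    ids = [line.split("\t")[1].strip()
           for line in Path(f"{prefix}.grm.id").read_text().splitlines() if line]
    n = len(ids)
    mat = np.zeros((n, n))
    n_snps = 0
    for line in Path(f"{prefix}.grm").read_text().splitlines():
        i, j, n_snps, val = line.split("\t")
        mat[int(i) - 1, int(j) - 1] = mat[int(j) - 1, int(i) - 1] = float(val)
    # The denominator is not part of the GCTA layout; store SNP count and a
    # unit denominator placeholder.
    return GRM(ids, mat, denominator=1.0, set_name="loaded", n_snps=int(n_snps))
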