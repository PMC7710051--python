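"""Synthetic genotypes, annotation, phenotypes and abstract corpora.

The generator emulates the inputs of a feature-partitioned genomic
prediction study: a dense biallelic SNP panel across several autosomes with
genes tiled along each chromosome, an additive architecture in which a
chosen fraction of the genetic variance sits on QTL inside a designated
feature SNP set, categorical fixed effects, and a literature corpus with
gene symbols planted at known frequencies among lowercase decoys.

SNP effects are drawn with per-set variances scaled by ``f_tm`` after
2p(1-p) allele-frequency standardisation, so the expected variance
bookkeeping matches the VanRaden GRM scaling used downstream.  SNPs are
independent by default (no LD); an optional block-copy mode repeats a latent
haplotype within blocks for LD-sensitive checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import (AbstractCorpus, GeneAnnotation, GeneLexicon, GenotypePanel,
                 PhenotypeTable, SNPPartition)


@dataclass
class ArchitectureSpec:
    """Additive genetic architecture for :func:`simulate_phenotype`.

    h2
        Target narrow-sense heritability of the phenotype (before fixed
        effects are added).
    n_qtl
        Number of causal SNPs.
    f_tm
        Fraction of the additive genetic variance carried by QTL inside the
        feature ("tm") SNP set.
    fixed_effects
        Mapping covariate name -> {level: additive offset on the trait
        scale}; levels are assigned to individuals uniformly at random.
    var_p
        Phenotypic variance scale (genetic + residual), trait units squared.
    """

    h2: float
    n_qtl: int
    f_tm: float = 0.0
    fixed_effects: dict = field(default_factory=dict)
    var_p: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ParameterError("h2 must be in [0, 1]")
        if not 0.0 <= self.f_tm <= 1.0:
            raise ParameterError("f_tm must be in [0, 1]")
        if self.n_qtl < 0:
            raise ParameterError("n_qtl must be non-negative")
        if self.var_p <= 0:
            raise ParameterError("var_p must be positive")


@dataclass
class TruthSet:
    """Ground truth recorded by :func:`simulate_phenotype`."""

    effects: np.ndarray          # per-SNP allele substitution effects (dosage scale)
    tbv: np.ndarray              # true breeding values, trait units
    realized_h2: float           # var(TBV) / var(TBV + e) in this sample
    qtl_idx: dict                # {"tm": array, "exp": array} of SNP offsets
    sigma2_g: float              # generating additive variance
    sigma2_e: float              # generating residual variance


def simulate_genotypes(n: int, m: int, n_chrom: int = 10,
                       maf_range: tuple = (0.05, 0.5), seed: int = 0,
                       gene_fraction: float = 0.4, gene_snps: int = 10,
                       snp_spacing: int = 1000, ld_blocks: int | None = None,
                       ) -> tuple[GenotypePanel, GeneAnnotation]:
    """Simulate a biallelic dosage panel plus a tiled gene annotation.

    Dosages are Binomial(2, p_j) per SNP with p_j ~ Uniform(maf_range);
    genes of ``gene_snps`` SNPs are tiled along each chromosome so that
    about ``gene_fraction`` of SNPs fall inside genes, the remainder in
    intergenic gaps between named gene pairs.  With ``ld_blocks`` set, the
    SNPs of each block copy a latent haplotype pair, giving within-block LD.
    Deterministic under ``seed``.
    """
    lo, hi = maf_range
    if not (0.0 < lo < 0.5 and 0.0 < hi <= 0.5 and lo <= hi):
        raise ParameterError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
    if n_chrom < 1 or m < n_chrom:
        raise ParameterError("need at least one SNP per chromosome")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)

    if ld_blocks:
        # Block-copy LD: two latent haplotypes per block, each SNP copies one
        # of them with a small flip probability.
        dosage = np.empty((n, m), dtype=np.int8)
        bounds = np.linspace(0, m, ld_blocks + 1).astype(int)
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            hap = rng.binomial(1, p[b0:b1][None, :], size=(2 * n, b1 - b0))
            anchor = rng.binomial(1, 0.5, size=(2 * n, 1))
            latent = np.where(anchor == 1, hap[:, :1], 1 - hap[:, :1])
            flip = rng.random((2 * n, b1 - b0)) < 0.1
            alle = np.where(flip, hap, np.broadcast_to(latent, hap.shape))
            dosage[:, b0:b1] = (alle[:n] + alle[n:]).astype(np.int8)
    else:
        dosage = rng.binomial(2, p, size=(n, m)).astype(np.int8)

    # SNP map: m split as evenly as possible across chromosomes.
    counts = np.full(n_chrom, m // n_chrom)
    counts[: m % n_chrom] += 1
    chroms, positions, ids = [], [], []
    for c, mc in enumerate(counts, start=1):
        chroms += [str(c)] * mc
        positions += list(np.arange(1, mc + 1) * snp_spacing)
        ids += [f"rs{c}_{j}" for j in range(mc)]
    snps = pd.DataFrame({"snp": ids, "chrom": chroms, "pos": positions,
                         "a1": "A", "a2": "B"})
    samples = [f"id{i:05d}" for i in range(n)]
    panel = GenotypePanel(samples, snps, dosage)

    # Tile genes: blocks of gene_snps SNPs inside genes, separated by gaps
    # sized to hit gene_fraction overall.
    gap_snps = max(1, round(gene_snps * (1 - gene_fraction) / max(gene_fraction, 1e-9)))
    rows = []
    g = 0
    for c, mc in enumerate(counts, start=1):
        pos_c = np.arange(1, mc + 1) * snp_spacing
        j = 0
        while j < mc:
            j_end = min(j + gene_snps, mc)
            rows.append({"symbol": f"G{g:04d}", "chrom": str(c),
                         "start": int(pos_c[j]), "end": int(pos_c[j_end - 1])})
            g += 1
            j = j_end + gap_snps
    ann = GeneAnnotation(pd.DataFrame(rows))
    return panel, ann


def simulate_phenotype(panel: GenotypePanel, partition: SNPPartition,
                       spec: ArchitectureSpec, seed: int = 0,
                       ) -> tuple[PhenotypeTable, TruthSet]:
    """Simulate an additive phenotype with feature-enriched QTL.

    QTL are placed in the ``tm`` and ``exp`` sets in proportion to set size;
    standardized effect variances within each set are scaled so the expected
    genetic-variance share on tm-set QTL equals ``spec.f_tm``.  Residual
    variance is set so the expected heritability equals ``spec.h2``.
    Categorical fixed effects are added as level offsets.
    """
    rng = np.random.default_rng(seed)
    n, m = panel.dosage.shape
    if spec.n_qtl > m:
        raise ParameterError("more QTL than SNPs")
    tm = partition.indices("tm") if "tm" in partition else np.array([], dtype=int)
    exp_set = partition.indices("exp") if "exp" in partition else np.arange(m)
    if spec.f_tm > 0 and tm.size == 0:
        raise ParameterError("f_tm > 0 requires a non-empty tm set")

    sigma2_g = spec.h2 * spec.var_p
    sigma2_e = (1.0 - spec.h2) * spec.var_p

    dos = panel.dosage.astype(float)
    dos[panel.dosage == np.int8(-9)] = np.nan
    p_hat = np.nanmean(dos, axis=0) / 2.0

    effects = np.zeros(m)
    qtl_idx = {"tm": np.array([], dtype=int), "exp": np.array([], dtype=int)}
    if spec.n_qtl > 0 and sigma2_g > 0:
        share = {"tm": spec.f_tm, "exp": 1.0 - spec.f_tm}
        sets = {"tm": tm, "exp": exp_set}
        # Allocate QTL counts proportionally to set size (>=1 where the set
        # carries variance and is non-empty).
        counts = {}
        for name, idx in sets.items():
            frac = idx.size / m
            c = int(round(spec.n_qtl * frac))
            if share[name] > 0 and idx.size > 0:
                c = max(1, c)
            counts[name] = min(c, idx.size)
        for name, idx in sets.items():
            c = counts[name]
            if c == 0 or share[name] == 0:
                continue
            chosen = rng.choice(idx, size=c, replace=False)
            chosen.sort()
            qtl_idx[name] = chosen
            u = rng.normal(0.0, np.sqrt(share[name] * sigma2_g / c), size=c)
            het = 2 * p_hat[chosen] * (1 - p_hat[chosen])
            het = np.where(het > 0, het, np.nan)
            a = u / np.sqrt(het)
            a = np.nan_to_num(a)  # monomorphic QTL carry no variance
            effects[chosen] = a

    centered = np.nan_to_num(dos - 2 * p_hat)  # missing -> mean (0 centered)
    tbv = centered @ effects
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=n) if sigma2_e > 0 else np.zeros(n)

    y = tbv + e
    df = pd.DataFrame({"id": panel.samples, "y": y})
    categorical = []
    for cov, levels in spec.fixed_effects.items():
        names = list(levels)
        assign = rng.integers(0, len(names), size=n)
        df[cov] = [names[a] for a in assign]
        df["y"] += np.array([levels[names[a]] for a in assign])
        categorical.append(cov)
    df["y_missing"] = False
    df["covariate_missing"] = False

    var_tbv = float(np.var(tbv))
    denom = float(np.var(tbv + e))
    realized_h2 = var_tbv / denom if denom > 0 else 0.0
    pheno = PhenotypeTable(df, "id", "y", categorical, [])
    truth = TruthSet(effects, tbv, realized_h2, qtl_idx, sigma2_g, sigma2_e)
    return pheno, truth


_FILLER = ("the marbling of beef cattle was measured and growth traits were "
           "recorded across farms while feed intake and meat tenderness were "
           "assessed in steers under different diets").split()

_CAPS_NOISE = ["TIAB", "QPCR", "ANOVA2", "RNAX", "GWASX"]


def simulate_corpus(lexicon: GeneLexicon, planted: dict, decoys: list,
                    n_docs: int, seed: int = 0, trait: str = "TRAIT",
                    ) -> tuple[AbstractCorpus, dict]:
    """Plant gene symbols at exact counts inside filler abstracts.

    Each planted symbol occurs exactly its planted count across the corpus,
    surrounded by lowercase filler prose, lowercase decoy words, and
    all-caps tokens absent from the lexicon.  Returns the corpus and the
    truth table (symbol -> planted count).
    """
    bad = [s for s in planted if lexicon.resolve(s.upper()) is None]
    if bad:
        raise ParameterError(f"planted symbols not in lexicon: {bad}")
    if n_docs < 0:
        raise ParameterError("n_docs must be non-negative")
    rng = np.random.default_rng(seed)
    if n_docs == 0:
        return AbstractCorpus([]), {}

    caps_noise = [t for t in _CAPS_NOISE if lexicon.resolve(t) is None]
    words_per_doc = [list(rng.choice(_FILLER, size=12)) for _ in range(n_docs)]
    for w in words_per_doc:
        w.extend(rng.choice(decoys, size=min(len(decoys), 3)) if decoys else [])
        w.extend(rng.choice(caps_noise, size=2))
    for sym, count in planted.items():
        docs = rng.integers(0, n_docs, size=count)
        for d in docs:
            words_per_doc[d].append(sym.upper())
    records = []
    for i, w in enumerate(words_per_doc):
        rng.shuffle(w)
        cut = max(1, len(w) // 6)
        records.append({"id": f"doc{i:05d}", "title": " ".join(w[:cut]) + ".",
                        "abstract": " ".join(w[cut:]) + ".", "trait": trait})
    return AbstractCorpus(records), dict(planted)
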