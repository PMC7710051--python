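# gfblup — genomic-feature GBLUP with text-mined SNP panels

`gfblup` is a research pipeline for **feature-partitioned genomic
prediction** in livestock. The idea: gene symbols mined from the titles and
abstracts of trait-related publications mark genomic regions that are more
likely to harbour causal variants; SNPs inside (and immediately flanking)
those genes are split out of a dense panel into their own genomic
relationship matrix, and weighting that matrix separately in a two-GRM GBLUP
model can improve the accuracy of genomic estimated breeding values (GEBVs)
for traits such as carcass weight, backfat thickness, eye muscle area, shear
force and intramuscular fat.

It is written for quantitative geneticists who want a transparent,
fully-testable implementation of that workflow: plain NumPy/SciPy linear
algebra, PLINK-format I/O, and a synthetic-data generator so every stage can
be validated offline with known ground truth.

## The model

With dosage matrix column-centered by twice the allele frequency
(M = W − 2p), the VanRaden genomic relationship matrix over a SNP set is

    G = M M′ / (2 Σⱼ pⱼ(1 − pⱼ)).

Three mixed models are supported (X b are fixed effects):

1. `y = Xb + g_all + e`,  g_all ~ N(0, G_all σ²_all)   — all SNPs
2. `y = Xb + g_−t + e`,   g_−t ~ N(0, G_−t σ²_−t)      — complement panel
3. `y = Xb + g_−t + g_t + e`                            — two GRMs, the
   feature (text-mined) set weighted separately

Variance components are estimated by **AI-REML** (average-information
updates with step-halving and an EM fallback, so the restricted likelihood
never decreases). Heritabilities follow the model-specific formulas, e.g.
model 3: `h² = (σ²_t + σ²_−t) / (σ²_t + σ²_−t + σ²_E)`. GEBVs come from the
mixed-model equations

    [ X′X      X′Z        ] [b]   [X′y]
    [ Z′X  Z′Z + λ G⁻¹    ] [û] = [Z′y],   λ = σ²_E / σ²_g,

with the analogous three-block system for model 3 (final GEBV = û_−t + û_t).
Individuals without phenotypes enter through all-zero Z columns. A
leave-one-chromosome-out (LOCO) mixed-model scan tests candidate SNPs with
Bonferroni (0.05/m) and suggestive (0.1/m) thresholds, and 10-fold
cross-validation reports accuracy as r(GEBV, y_c), the correlation with
fixed-effect-corrected phenotypes.

## Worked example

```python
import numpy as np
from gfblup import *

# synthetic study: 400 animals, 2000 SNPs, genes tiled along 5 chromosomes
panel, genes = simulate_genotypes(n=400, m=2000, n_chrom=5, seed=7)

# a corpus with known planted gene mentions, mined back exactly
lex = GeneLexicon(set(genes.table["symbol"].iloc[::15][:8]))
planted = {s: 4 + i for i, s in enumerate(sorted(lex.symbols))}
corpus, _ = simulate_corpus(lex, planted, ["impact", "pigs"], n_docs=25, seed=7)
mined = mine_genes(corpus, lex)
part = select_snps(mined, genes, panel, include_intergenic=True)  # 225 tm SNPs

# trait with h2 = 0.4, 70% of genetic variance on the feature set
spec = ArchitectureSpec(h2=0.4, n_qtl=150, f_tm=0.7)
pheno, truth = simulate_phenotype(panel, part, spec, seed=8)

grms = [build_grm(panel, part.indices(s), set_name=s) for s in ("exp", "tm")]
res = GenomicMixedModel.from_dataframe(pheno, grms).fit()
print(res.summary())
```

```
Genomic mixed model (AI-REML + GBLUP)
==============================================
n individuals:      400
genomic components: exp, tm
REML log-likelihood: -188.6352   iterations: 4   converged: True
----------------------------------------------
component           sigma2          SE
exp                 0.1120      0.1285
tm                  0.2836      0.0742
e                   0.5999      0.1378
----------------------------------------------
h2 = 0.3974  (rounded: 0.40)
lambda: exp=5.356, tm=2.116
```

The fit recovers the simulated architecture: total genomic variance
0.112 + 0.284 ≈ 0.40 (the target h² on a unit-variance trait), with the
feature set carrying most of it, and the smaller σ²_t…σ²_−t split mapping to
per-component shrinkage weights λ. Cross-validated accuracy for the four
standard configurations on shared folds:

```python
print(compare_models(panel, pheno, part, k=5, seed=1,
                     varcomp_policy="global").to_string(index=False))
```

```
 model   mean_r       se
    Im 0.178699 0.036138
   exp 0.073118 0.046420
exp+tm 0.313289 0.031046
exp+em 0.226865 0.033744
```

Dropping the feature SNPs (`exp`) loses most of the signal; weighting them
separately (`exp+tm`) beats both the single full-panel GRM (`Im`) and the
size-matched evenly-spaced control (`exp+em`) — the qualitative pattern the
feature-partitioned model is designed to produce when the enrichment is
real.

## Command line

Every stage is also a subcommand of the `gfblup` CLI:
`simulate`, `mine`, `grm`, `reml`, `gblup`, `gwas`, `cv`, `run` (full
pipeline from a YAML config; `gfblup config --init pipeline.yaml` writes the
defaults).

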