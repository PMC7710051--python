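# Methods

## Scope and data model

The package implements a feature-partitioned genomic prediction workflow:
gene symbols are mined from an abstract corpus, a dense SNP panel is
partitioned into a feature set (SNPs inside or flanking mined genes, "tm")
and its complement ("exp"), VanRaden genomic relationship matrices (GRMs)
are built per set, variance components are estimated by AI-REML, GEBVs are
predicted by single- or two-GRM GBLUP, candidate SNPs are tested with a
LOCO mixed model, and prediction accuracy is measured by k-fold
cross-validation as r(GEBV, y_c).

Genotypes are integer allele-1 dosages (0/1/2) with a dedicated missing
sentinel (−9), read and written as PLINK BED/BIM/FAM (SNP-major v1).
Positions are 1-based; gene intervals are inclusive on both ends; internal
indexing is 0-based map order. SNPs on sex chromosomes are dropped at read
time by default. Duplicate SNP ids are rejected rather than deduplicated.

## Text mining

Tokens are produced by splitting on any non-alphanumeric character, so
"IGF-1" yields `IGF` deterministically. A token is a candidate symbol if it
is ≥2 characters of uppercase letters/digits with at least one letter; this
all-caps rule is what excludes ordinary words that collide with gene symbols
in lowercase prose ("impact", "pigs"). Candidates are matched
case-sensitively against an uppercased lexicon with optional aliases.

Frequency counts **occurrences** by default (every token hit across titles
and abstracts); a per-article mode is available behind the `count` switch
since published frequency tables do not disambiguate the two. Feature SNPs
are those inside a mined gene's interval plus, when enabled (default), SNPs
in intergenic intervals whose nearest flanking gene on either side is mined
— intergenic regions carry regulatory elements, and loci are conventionally
named GENE1–GENE2 by their flanking genes. The breadth of the intergenic
interval is the full nearest-gene gap; a `flank_cap_bp` limit is offered
because the appropriate breadth is genuinely open.

## GRM and quality control

`G = MM′ / (2Σ pⱼ(1−pⱼ))` with M the dosage matrix centered by 2pⱼ.
Frequencies are always sample-estimated from the post-QC panel (no external
base-population frequencies are assumed). Missing dosages are mean-imputed
(centered zero), the standard treatment, which preserves the exact
zero-row-sum identity. Monomorphic SNPs contribute zero to numerator and
denominator. Numerators and denominators add over disjoint SNP sets, giving
the exact union identity `G_union = (d₁G₁ + d₂G₂)/(d₁ + d₂)` used to verify
LOCO matrices.

QC removes SNPs with `min(p, 1−p) < maf_min` or missing-call fraction
`> max_missing` (the PLINK `--geno` reading of "call rate"); both filters
are idempotent and the report reconciles exactly.

A GRM built with sample frequencies is singular by construction (rows sum
to zero). Wherever G⁻¹ is required and plain Cholesky inversion fails — or
silently returns an inaccurate inverse, which is detected with a probe
column — the matrix is blended as `0.95·G + 0.05·I` before inversion, the
smallest intervention consistent with the printed equations. In
cross-validation the blended matrix (when blending is needed) is used by
both the GLS and MME fold routes so the two solve the same model.

## AI-REML

For `V = Σₖ σ²ₖ Gₖ + σ²_E I` the restricted log-likelihood (up to the
model-free constant) is `−½[log|V| + log|X′V⁻¹X| + y′Py]`. Updates use the
average-information matrix `AIₖₗ = ½(Py)′Gₖ P Gₗ(Py)`; a step that leaves
the feasible region or decreases the likelihood is halved (up to 12 times),
then replaced by a multiplicative EM-style update `σ²ₖ ← σ²ₖ·(y′PGₖPy)/tr(PGₖ)`,
so accepted iterations never decrease the objective and the best-seen point
is returned. Defaults: tolerance 1e-8 on the log-likelihood change and 1e-6
relative on parameters, at most 200 iterations, component floor
`1e-8·var(y)`; initialisation puts half the projected phenotypic variance
on the residual and splits the rest equally among genomic components (scale
free; the reference tooling's own defaults are comparable). Standard errors
come from the inverse AI matrix at convergence; no profile intervals. All
dense algebra goes through Cholesky factorizations; explicit inverses are
formed only where a contract requires G⁻¹ itself.

Heritability: model 1 `σ²_all/(σ²_all+σ²_E)`, model 2 `σ²_−t/(σ²_−t+σ²_E)`,
model 3 `(σ²_t+σ²_−t)/(σ²_t+σ²_−t+σ²_E)`; the residual notation is read as
σ²_E throughout. Reported values are carried at full precision with a
2-decimal half-away-from-zero presentation.

## GBLUP and the MME/GLS pair

`solve_mme` assembles the symmetric coefficient matrix (treatment-coded
full-rank fixed effects; λₖ = σ²_E/σ²ₖ always derived from a variance
estimate, never free inputs) and solves it by Cholesky with iterative
refinement until the normal-equation residual is below 1e-8·‖RHS‖.
Unphenotyped individuals are handled by all-zero Z columns exactly; their
GEBVs emerge from the G-propagation inherent in the equations. The
independent oracle `gls_blup_oracle` computes the same quantities from the
dense covariance `V = Σ ZGₖZ′σ²ₖ + Iσ²_E`; agreement of the two routes to
1e-8 on random instances is the package's central correctness property and
an acceptance-level test.

## GWAS

Phenotypes are pre-adjusted by OLS (`y_c = y − Xb̂ + ȳ`, location and scale
retained; adjustment is idempotent). The scan fits, per candidate SNP, an
intercept plus dosage by GLS under `V = G_loco σ²_g + I σ²_E`, with variance
components estimated once per left-out chromosome (the two-stage MLMA
scheme), a refit intercept per SNP, and a two-sided Wald p-value under the
normal approximation. Candidate missing dosages are mean-imputed;
monomorphic candidates are flagged, not fatal. Bonferroni 0.05/m and
suggestive 0.1/m are the only multiplicity corrections.

## Cross-validation

Folds are simple random permutations split as evenly as possible (sizes
differ by ≤1), deterministic under the seed; no family stratification is
applied (none is assumed by the design, and relatedness structure is a
known driver of accuracy — see limitations). Variance components are
re-estimated on each training fold by default; a `global` policy estimates
them once on all data and shares them across folds, which is what the
acceptance-scale comparisons use (the comparisons are between
configurations on identical folds, where the mild leakage is shared).
Accuracy correlates validation GEBVs with y_c computed from the
fixed-effect adjustment on all data. Each fold is solved through the GLS
route (identical to the zero-Z-column MME, factorizing an n_train matrix
instead of the much larger MME); `solver="mme"` routes through the explicit
equations and is tested to agree.

The evenly-spaced control draws `count` SNPs at stride ⌊M/count⌋ from a
seed-chosen offset and is partitioned against its own complement,
symmetric with the feature/complement split.

## Synthetic data

The generator emulates the study conditions end to end: biallelic dosages
Binomial(2, pⱼ) with pⱼ ~ Uniform(0.05, 0.5) across 10 autosomes by
default; genes of 10 SNPs tiled so ~40% of SNPs are genic (a realistic
genic fraction for a mammalian genome at this marker density), the rest
intergenic between named gene pairs; QTL effects drawn normal per set with
variances scaled by the feature share f_tm after 2p(1−p) standardisation,
so expected variance bookkeeping matches the GRM scaling exactly; residual
variance set from the target h² on a unit phenotypic scale; categorical
fixed effects as additive level offsets; corpora with symbols planted at
exact counts among lowercase filler, lowercase decoys and all-caps
non-lexicon noise. SNPs are independent by default; a block-copy LD mode
exists for LD-sensitive checks.

What the generator does **not** emulate: coalescent-realistic LD, pedigree
or half-sib family structure, selection, non-additive effects, and
non-normal effect-size distributions (the normal choice is a stand-in, not
an inference about real trait architectures). Passing tests therefore
demonstrate correctness of the estimators and the qualitative
feature-enrichment mechanism, not real-data accuracy levels: with
independent SNPs and unrelated individuals, absolute CV accuracies are
bounded by n/m and sit well below values achievable in half-sib livestock
populations.

## Problem sizes used in the validation suite

Chosen once as desk-scale study conditions: MME/GLS equivalence on 50
random instances (n ≤ 200, 1 and 2 GRMs); AI-REML recovery at σ²_g = 2,
σ²_E = 1, n = 500, 50 replicates, with a grid+Nelder–Mead oracle on 5
subsampled n = 80 instances; GWAS calibration on 20 replicates × 2000 null
candidate SNPs (n = 400, polygenic h² = 0.3 on the left-out chromosome);
text-mining round trips on 100 random corpora; and the accuracy comparison
at n = 1500, m = 5000, |tm| = 250, h² = 0.3, f_tm = 0.8 over 10 seeds
(null arm f_tm = 0 over 5 seeds). Boundary-collapsed variance components
are compared to the oracle with an absolute floor of 1e-4·var(y), since
relative error is undefined at the zero boundary.

## Known limitations

- Two genomic components at most; no covariance between random effects,
  no multi-trait REML, no ssGBLUP/H-matrix, no SNP-BLUP back-solving.
- The Wald normal approximation slightly understates p at small n compared
  with an exact t or LRT.
- GCTA-style text GRM persistence does not carry the VanRaden denominator;
  reloaded matrices are usable for fitting but not for union-identity
  arithmetic.
- The homonym problem of symbol-based mining (ordinary all-caps
  abbreviations that collide with real gene symbols, e.g. SST) is inherited
  by design; no named-entity disambiguation is attempted.
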