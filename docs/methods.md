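# Methods

## Generative model of the synthetic cohorts

The generator (`coexpci.synthetic`) draws, for each cohort:

* **Genotypes.** Minor-allele dosages i.i.d. Binomial(2, MAF) per SNP —
  exact Hardy-Weinberg proportions — with MAFs uniform on a configurable
  range (default 0.20-0.48, the range spanned by typical common-variant
  panels). SNPs are in linkage equilibrium by default; a block-LD helper
  (`simulate_ld_block_genotypes`: consecutive SNPs copy a block anchor,
  each call independently re-drawn with probability 0.05) exists solely to
  exercise LD pruning.
* **Latent factor.** `L_i = Σ_s β_s (d_is − 2p_s) + ε_i`, with ε scaled so
  `var(L) = 1`. The default is 8 causal SNPs with equal β = 0.36, chosen so
  the fitted PCI's training R² against the eigengene averages ≈ 0.38 under
  the default screen (see "PCI" below). The causal SNPs are placed inside
  the ±100 kb windows of module genes so the candidate-window step retains
  them.
* **Module expression.** Gene g of the 85-gene module follows
  `x_ig = λ_g L_i + Σ_c γ_cg c_i + σ ε_ig` with loadings λ uniform on
  (0.4, 0.9) (the seed-gene analogue pinned to the upper end so eigengene
  orientation is stable). The common residual SD σ is solved by bisection
  on the population correlation matrix `a aᵀ + diag(1 − a²)`,
  `a_g = λ_g/√(λ_g² + σ²)`, so that its top-eigenvalue fraction equals
  `pc1_target` (default 0.325). The target is attainable for any value in
  (1/p, 1); out-of-range targets raise an error naming the bound.
* **Confounds.** Age ~ U(18, 78) and binary sex act linearly on every gene
  (per-gene effects drawn from small ranges). They stand in for the
  demographic structure a real preprocessing step must remove; the
  pipeline's residualization stage is responsible for removing them before
  network construction, and the PC1 target refers to the confound-adjusted
  module.
* **Background genes.** Independent unit-variance noise plus the same
  confound mechanism — deliberately structureless, so module detection is
  tested against a null background rather than a competing module.
* **Replication cohort.** Fresh samples reusing the discovery truth
  (loadings, SNP panel, allele orientation), with 5 of 85 module probes
  dropped, quality scores drawn lower (U(4.5, 9) vs U(7, 9.5)), and causal
  effects rescaled so the population R² between the frozen-weight PCI and
  the recomputed eigengene is 0.15 — a deliberately weaker, noisier cohort.
* **Clinical cohorts.** Genotypes and phenotypes only (no expression):
  `improvement = ρ·L + √(1−ρ²)·η` with ρ = `clinical_effect` (default 0.4),
  responders defined by a median split of improvement. The split quantile
  is configurable; the median default maximizes the power of the
  rank-based responder comparison.

What the generator does **not** emulate: realistic transcriptome-wide
covariance (background genes are independent), multiple competing modules,
LD panels with realistic decay, population stratification, non-Gaussian
expression noise, and cohort-specific batch structure. Passing tests
therefore demonstrate that the pipeline's statistics behave correctly under
the stated single-factor model, not that the pipeline is robust to every
pathology of real expression data.

## Pipeline stages and numerical choices

**Preprocessing.** Samples are kept if quality > threshold (strict, so a
score exactly at the threshold is dropped). Each gene is replaced by OLS
residuals on intercept + covariates in one batched least-squares solve;
genes with missing values are dropped with a logged count rather than
imputed. Rank-deficient designs fail with the collinear columns named.

**Network.** Pearson correlation; unsigned soft-thresholded adjacency
`|r|^β` (signed `((1+r)/2)^β` available). The soft power is the smallest
grid value whose scale-free fit R² ≥ 0.8, computed by regressing log10
bin frequency on log10 mean connectivity over 10 equal-width connectivity
bins; near-constant connectivity short-circuits to R² = 0, and if no power
qualifies the best-R² power is used with a warning. Topological overlap is
the standard matrix form; module detection is average-linkage clustering
of 1 − TOM with a **static cut** at `cut_height ×` (max merge height) and
relabeling of clusters below `min_module_size` (default 20) to the grey
label 0 — a deliberate, fully deterministic replacement for dynamic tree
cutting, with ties broken by smallest member position. On the default
synthetic cohort the scale-free criterion selects power 4 and the default
cut 0.998 recovers the planted module with Jaccard ≈ 0.98 (and degrades gracefully when the selector lands on power 5). The eigengene
is the first PC of the gene-standardized member submatrix (unit-variance
scores, ddof = 1), sign-oriented so its correlation with the seed gene
(fallback: mean member correlation) is non-negative.

**Co-eQTL screen.** Per SNP, OLS of the ME on additive dosage, two-sided t
test on the slope; monomorphic or low-n SNPs are flagged, never silently
dropped. Covariates are omitted by default because the ME is computed from
already-residualized expression. Candidate SNPs are restricted to ±100 kb
closed windows around module genes (chromosome-name `chr` prefixes are
normalized).

**Selection.** Greedy LD pruning in ascending-p order at r² < 0.2 (ties by
SNP id), then either the fixed threshold p < 0.005 (default) or the
plateau rule: add pruned SNPs in ascending p, refit, and stop when the
**adjusted** training R² gain falls below `plateau_eps` = 0.005 twice in a
row. The adjustment (≈ 2 group-mean parameters per SNP) matters: raw
training R² rises by ≈ 2/n for every null SNP added, which at cohort sizes
of a few hundred would defeat a fixed 0.005 epsilon.

**PCI.** Weights are centered genotype-group means of the training ME.
Genotype groups smaller than `min_group` = 5 are merged into the
heterozygote group (homozygote → heterozygote) before computing means,
because tiny-group means are unstable; SNPs collapsing to one group are
dropped with a warning. Scoring sums the weights of an individual's
genotypes; a missing genotype contributes 0 — the centered-null
contribution — keeping cohort sizes stable, and samples missing more than
half the model SNPs are flagged. A SNP whose recorded minor allele
disagrees with the scoring cohort's is dose-flipped with a warning. The
weighting sits behind a single function so alternative schemes (e.g.
rank-based) can be swapped.

**Cross-validation.** K-fold (default 5) with full per-fold re-selection
(scan, pruning and thresholding on the training portion only) — the
stricter of the two plausible protocols; weight-only refitting is
available by flag. Folds with empty models are excluded from pooling and
counted. **Replication** recomputes the eigengene on the module genes
present in the replication cohort (≥ 50% required by default), scores with
the frozen training weights — replication expression can never influence
the scores — and reports a one-tailed p for r > 0 (the direction is a
prior claim), overall and stratified by quality > 6.

**Phenotype association.** OLS or Huber M-estimation (tuning constant
1.345, IRLS to 1e-8/50 iterations) for ROI-style linear association; the
two-level repeated-measures LOAD × PCI interaction is computed exactly as
the difference-score regression (for a two-level within factor the
interaction F equals t² of the difference slope), with per-load post-hoc
regressions attached and the family α = 0.025 reported as metadata only.
Gene-set enrichment is the exact hypergeometric upper tail summed in
log-space; the background universe is always an explicit argument.
Spearman uses mid-ranks with the t approximation. ROC/AUC comes from
mid-ranks (ties get half credit) with a tie-corrected normal Mann-Whitney
p, one-tailed for AUC > 0.5, without continuity correction. BH-FDR is the
standard step-up. Near-perfect fits (numerically zero residual variance)
short-circuit the t statistic to its degenerate limit instead of dividing
rounding error by rounding error.

**Reproducibility.** All pipeline randomness derives from one run seed via
`stage_seed(seed, label)` = SHA-256 of `"{seed}:{label}"` mod 2³¹. The
pipeline runner writes each stage's outputs before the next stage starts
and records SHA-256 checksums, config hash and warnings in a manifest.

## Problem sizes used by the test suite and acceptance script

Module recovery runs the full network chain on 10-20 cohorts of 1,000
genes × 200 samples; screen calibration uses 1,000 null SNPs at n = 200 and
1,000 single-SNP power replicates; PCI validation uses 20 cross-validated
cohorts, 100 replication cohorts of n = 50 and 200 clinical cohorts of
n = 87. These sizes keep a full run to seconds-to-minutes on one CPU while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* The static tree cut is simpler than canonical dynamic tree cutting; on
  real data with nested module structure it may need manual cut tuning.
* The clinical responder-prediction margin is intrinsically thin at the
  default design (AUC ≈ 0.60 at n = 87 gives a one-sided sign test ~95%
  power), so the sign-stability check on the AUC hovers at its own
  threshold; the Spearman-based direction check is more stable.
* Group-mean PCI weights carry estimation noise that mildly attenuates
  out-of-cohort transfer relative to an oracle linear score.
* The minimal VCF reader handles biallelic GT-only records; dosage fields,
  phased half-calls and structural records are out of scope.
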