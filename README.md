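# coexpci

Co-expression module detection, co-eQTL screening and the **Polygenic
Co-expression Index (PCI)** — a tested, reusable pipeline for linking common
genetic variation to the coordinated expression of a gene set, and that
genetic summary to downstream phenotypes.

## The problem

Risk genes for complex brain disorders act through molecular pathways, and
co-expressed genes tend to be co-regulated. Given a seed gene of interest
(e.g. a receptor gene), one can:

1. identify the **co-expression module** containing the seed gene from a
   weighted gene co-expression network built on post-mortem expression data;
2. summarize the module's shared variation by its **module eigengene (ME)**
   — the first principal component of the gene-standardized module
   submatrix;
3. screen SNPs near module genes for association with the ME. A variant
   associated with co-expression of the whole set (rather than a single
   transcript) is a **co-eQTL**, a species of trans-eQTL;
4. combine the selected independent SNPs into a per-individual **PCI**:
   each genotype *g* of each SNP *s* receives the weight
   `w(s, g) = mean(ME | g at s) − mean(ME)` estimated in the training
   cohort, and `PCI_i = Σ_s w(s, g_is)`. The greater the PCI, the greater
   the predicted module co-expression — computable from genotypes alone,
   hence transferable to living cohorts with no brain tissue;
5. validate by cross-validation and frozen-weights replication in an
   independent expression cohort, and associate the PCI with behavioral,
   imaging-ROI and treatment-response phenotypes (Spearman rank
   correlation, ROC/AUC, repeated-measures interaction, BH-FDR).

Because the data sets such analyses run on are access-restricted, the
package ships a first-class **synthetic cohort generator** with the same
generative structure: Hardy-Weinberg genotypes, a latent co-expression
factor `L` with additive SNP effects (`var(L) = 1`), module genes
`x_g = λ_g L + confounds + noise` with the residual noise solved
numerically so the module's expected PC1 explained-variance fraction hits a
target (default 0.325), a replication cohort with partial probe overlap and
degraded RNA quality, and clinical improvement scores correlated with `L`.
Every stage of the pipeline is tested end to end against this generator's
ground truth.

## Worked example

Simulate a discovery cohort (200 samples; an 85-gene module among 1,000
genes; 8 causal SNPs among 50), then run the chain:

```sh
coexpci simulate --out cohort --seed 7
coexpci prep    --expr cohort/expression.tsv --covars cohort/covariates.tsv \
                --min-quality 6 --out resid.tsv
coexpci network --expr resid.tsv --seed-gene MOD0001 --out net
coexpci pci-fit --me net/eigengene.tsv --genotypes cohort/genotypes.tsv \
                --snp-meta cohort/snp_meta.tsv --gene-coords cohort/gene_coords.tsv \
                --out pci
coexpci pci-cv  --me net/eigengene.tsv --genotypes cohort/genotypes.tsv \
                --seed 7 --out cv.json
coexpci assoc   --pci pci/scores.tsv --pheno cohort/phenotypes.tsv --out assoc.tsv
```

Output printed by this session:

```
wrote resid.tsv (1000 genes x 200 samples)
seed module: label 1, 85 genes, PC1 fraction 0.328
selected 5 SNPs; training R^2 = 0.287
out-of-fold r = 0.450 (one-tailed p = 1.16e-11)
```

The network step recovered the planted 85-gene module exactly, with its
eigengene explaining 32.8% of module variance. The co-eQTL screen selected
5 independent SNPs at p < 0.005 (±100 kb windows around module genes,
greedy LD pruning at r² < 0.2); their genotype weights predict the ME with
training R² = 0.29, and the association survives 5-fold cross-validation in
which SNPs are re-selected per fold (pooled out-of-fold r = 0.45). The
`assoc.tsv` table then reports the clinical chain on the simulated
phenotypes, e.g.

```
test                  estimate  stat   p       sidedness  n
spearman_improvement  0.160     2.28   0.024   two        200
roc_responder         0.557     1.38   0.083   one        200
```

i.e. greater PCI goes with greater treatment improvement (ρ = 0.16,
p = 0.024) and responder prediction is above chance (AUC = 0.56). A single
`coexpci run --config pipeline.yaml` executes the whole chain (including
optional risk-gene enrichment and frozen-weights replication) and writes a
checksummed run manifest.

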