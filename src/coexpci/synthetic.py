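"""Synthetic cohort generator with the generative structure the analysis assumes.

The generator produces discovery, replication and clinical cohorts from a
single-factor model of module co-expression:

* SNP dosages are drawn under Hardy-Weinberg equilibrium at configured
  minor-allele frequencies, in linkage equilibrium by default.
* A latent co-expression factor ``L`` receives additive contributions from a
  small set of causal SNPs plus Gaussian noise, scaled so var(L) = 1.
* Each module gene loads on ``L`` with a gene-specific loading; a common
  residual noise standard deviation is solved numerically so that the
  population first-principal-component explained-variance fraction of the
  module correlation matrix equals ``pc1_target`` (default 0.325).
* All genes additionally carry linear demographic confound effects (age and
  sex by default) that the preprocessing stage is expected to remove.
* Clinical improvement is generated with a configurable correlation to ``L``
  and dichotomised into responder labels by a quantile rule.

The replication cohort reuses the discovery truth (loadings, SNP panel,
allele orientation) with fresh samples, a configurable number of module
probes dropped, lower RNA-quality scores, and a weaker genetic effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CovariateTable, ExpressionMatrix, GenotypeMatrix, ValidationError

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "CohortTruth",
    "simulate_genotypes",
    "simulate_ld_block_genotypes",
    "simulate_cohort",
    "simulate_clinical_outcomes",
    "simulate_replication_cohort",
    "simulate_clinical_cohort",
    "solve_module_noise_sd",
]

# (name, distribution spec, per-gene effect range); age in years, sex in {0,1}
DEFAULT_CONFOUNDS: tuple = (
    ("age", ("uniform", 18.0, 78.0), (-0.01, 0.01)),
    ("sex", ("bernoulli", 0.5), (-0.4, 0.4)),
)


@dataclass
class CohortConfig:
    """Study-design parameters for one simulated cohort.

    Defaults encode the discovery regime the pipeline is designed around:
    199-ish post-mortem samples, an 85-gene module whose first principal
    component carries about a third of the module variance, and eight
    causal SNPs whose combined dose effect gives the polygenic score a
    training R^2 near 0.38 against the module eigengene.
    """

    n_samples: int = 200
    n_module_genes: int = 85
    n_background_genes: int = 915
    n_snps: int = 50
    n_causal_snps: int = 8
    maf_range: tuple[float, float] = (0.20, 0.48)
    causal_beta: float = 0.36
    loading_range: tuple[float, float] = (0.4, 0.9)
    pc1_target: float = 0.325
    confound_spec: Sequence = DEFAULT_CONFOUNDS
    probe_dropout: int = 5
    clinical_effect: float = 0.4
    responder_quantile: float = 0.5
    quality_range: tuple[float, float] = (7.0, 9.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_snps > self.n_snps:
            raise ValidationError("n_causal_snps must be <= n_snps")
        if not (0.0 < self.pc1_target < 1.0):
            raise ValidationError("pc1_target must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if abs(self.clinical_effect) > 1.0:
            raise ValidationError("clinical_effect must satisfy |effect| <= 1")


@dataclass
class CohortTruth:
    """Ground-truth record of the generative process, for tests and scoring."""

    latent: pd.Series
    module_gene_ids: list[str]
    seed_gene_id: str
    loadings: pd.Series
    causal_snp_ids: list[str]
    causal_betas: pd.Series
    noise_sd: float
    genetic_variance_share: float
    expected_pc1_fraction: float
    expected_me_latent_cor2: float


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    truth: CohortTruth
    phenotypes: pd.DataFrame | None = None
    config: CohortConfig | None = None


def simulate_genotypes(n_samples: int, snp_meta: pd.DataFrame, seed) -> GenotypeMatrix:
    """Draw SNP dosages i.i.d. from Hardy-Weinberg proportions.

    ``snp_meta`` is indexed by SNP id and must carry a ``maf`` column; each
    dosage is Binomial(2, maf), i.e. genotype frequencies
    ((1-p)^2, 2p(1-p), p^2) for minor-allele dose 0/1/2.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    mafs = snp_meta["maf"].astype(float)
    bad = mafs[(mafs <= 0.0) | (mafs > 0.5)]
    if len(bad):
        raise ValidationError(
            f"MAF outside (0, 0.5] for SNP {bad.index[0]!r} (maf={bad.iloc[0]})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    doses = rng.binomial(2, mafs.to_numpy()[None, :], size=(n_samples, len(mafs)))
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    frame = pd.DataFrame(doses.astype(float), index=samples, columns=snp_meta.index)
    return GenotypeMatrix(frame, snp_meta.copy())


def simulate_ld_block_genotypes(
    n_samples: int,
    snp_meta: pd.DataFrame,
    block_size: int,
    flip_prob: float = 0.05,
    seed=0,
) -> GenotypeMatrix:
    """Genotypes with block linkage disequilibrium, for exercising LD pruning.

    SNPs are grouped into consecutive blocks of ``block_size``; within a
    block every SNP copies the block anchor's dosage, except that each
    sample's call is independently re-drawn from HWE with probability
    ``flip_prob``, giving high but imperfect pairwise dosage r^2.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = simulate_genotypes(n_samples, snp_meta, rng)
    D = base.dosages.to_numpy()
    mafs = snp_meta["maf"].to_numpy(float)
    for j in range(D.shape[1]):
        anchor = (j // block_size) * block_size
        if j == anchor:
            continue
        redraw = rng.random(n_samples) < flip_prob
        D[:, j] = np.where(redraw, rng.binomial(2, mafs[j], n_samples), D[:, anchor])
    out = pd.DataFrame(D.astype(float), index=base.dosages.index, columns=base.dosages.columns)
    return GenotypeMatrix(out, snp_meta.copy())


def _population_module_correlation(std_loadings: np.ndarray) -> np.ndarray:
    a = std_loadings
    R = np.outer(a, a)
    np.fill_diagonal(R, 1.0)
    return R


def _pc1_fraction(loadings: np.ndarray, noise_sd: float) -> float:
    a = loadings / np.sqrt(loadings**2 + noise_sd**2)
    R = _population_module_correlation(a)
    top = np.linalg.eigvalsh(R)[-1]
    return float(top / len(a))


def solve_module_noise_sd(
    loadings: np.ndarray, pc1_target: float, tol: float = 1e-4
) -> float:
    """Bisection for the common residual SD meeting the PC1 variance target.

    The population correlation matrix of the module under the one-factor
    model is ``a a^T + diag(1 - a^2)`` with standardized loadings
    ``a_g = lambda_g / sqrt(lambda_g^2 + sd^2)``; its top-eigenvalue
    fraction decreases monotonically in ``sd`` from 1 (sd=0) to 1/p.
    """
    p = len(loadings)
    if pc1_target <= 1.0 / p:
        raise ValidationError(
            f"pc1_target={pc1_target} infeasible: must exceed 1/n_module_genes={1.0 / p:.4f}"
        )
    lo, hi = 1e-6, 1e3
    if _pc1_fraction(loadings, hi) > pc1_target:
        raise ValidationError("pc1_target unreachable: loadings too strong for target")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _pc1_fraction(loadings, mid) > pc1_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            break
    return 0.5 * (lo + hi)


def _expected_me_latent_cor2(loadings: np.ndarray, noise_sd: float) -> float:
    """Population squared correlation between module PC1 scores and the factor."""
    a = loadings / np.sqrt(loadings**2 + noise_sd**2)
    R = _population_module_correlation(a)
    vals, vecs = np.linalg.eigh(R)
    v = vecs[:, -1]
    lam1 = vals[-1]
    return float((v @ a) ** 2 / lam1)


def _draw_confounds(spec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, dist, _ in spec:
        kind = dist[0]
        if kind == "uniform":
            cols[name] = rng.uniform(dist[1], dist[2], size=n)
        elif kind == "bernoulli":
            cols[name] = rng.binomial(1, dist[1], size=n).astype(float)
        elif kind == "normal":
            cols[name] = rng.normal(dist[1], dist[2], size=n)
        else:
            raise ValidationError(f"unknown confound distribution {kind!r}")
    return pd.DataFrame(cols)


def _snp_panel(config: CohortConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene coordinates and SNP metadata with causal SNPs inside gene windows.

    Module genes are laid out one per megabase across chromosomes 1-22 with
    50 kb bodies. Causal SNPs land inside the +/-100 kb window of module
    genes; half of the null SNPs are placed in windows, half well outside.
    """
    n_genes = config.n_module_genes + config.n_background_genes
    gene_ids = [f"MOD{i + 1:04d}" for i in range(config.n_module_genes)] + [
        f"BG{i + 1:04d}" for i in range(config.n_background_genes)
    ]
    chrom = [str((i % 22) + 1) for i in range(n_genes)]
    start = [1_000_000 * ((i // 22) + 1) for i in range(n_genes)]
    coords = pd.DataFrame(
        {"gene": gene_ids, "chrom": chrom, "start": start, "end": [s + 50_000 for s in start]}
    ).set_index("gene")

    snp_ids = [f"snp{i + 1:04d}" for i in range(config.n_snps)]
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    rows = []
    for j in range(config.n_snps):
        if j < config.n_causal_snps:
            g = gene_ids[j % config.n_module_genes]
            pos = int(coords.loc[g, "start"]) + int(rng.integers(-100_000, 150_000))
            c = coords.loc[g, "chrom"]
        elif j % 2 == 0:
            g = gene_ids[int(rng.integers(0, config.n_module_genes))]
            pos = int(coords.loc[g, "start"]) + int(rng.integers(-100_000, 150_000))
            c = coords.loc[g, "chrom"]
        else:  # intergenic, outside every +/-100 kb window
            g = gene_ids[int(rng.integers(0, n_genes))]
            pos = int(coords.loc[g, "start"]) + 400_000 + int(rng.integers(0, 100_000))
            c = coords.loc[g, "chrom"]
        rows.append((c, max(pos, 1), "A", "G", mafs[j]))
    meta = pd.DataFrame(rows, index=snp_ids, columns=["chrom", "pos", "minor", "major", "maf"])
    return coords, meta


def _latent_factor(
    geno: GenotypeMatrix, causal_ids: list[str], betas: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    mafs = geno.meta.loc[causal_ids, "maf"].to_numpy(float)
    genetic_var = float(np.sum(betas**2 * 2 * mafs * (1 - mafs)))
    if genetic_var >= 1.0:
        raise ValidationError(
            f"causal effects explain {genetic_var:.3f} >= 1 of latent variance; reduce causal_beta"
        )
    doses = geno.dosages[causal_ids].to_numpy(float)
    genetic = (doses - 2 * mafs) @ betas  # centered at HWE expectation
    eps = rng.normal(0.0, math.sqrt(1.0 - genetic_var), size=len(genetic))
    return genetic + eps, genetic_var


def simulate_clinical_outcomes(
    latent: pd.Series, clinical_effect: float, responder_quantile: float = 0.5, seed=0
) -> pd.DataFrame:
    """Improvement scores correlated with the latent factor plus responder labels.

    improvement_i = effect * L_i + sqrt(1 - effect^2) * eta_i with standard
    normal eta; responders are samples whose improvement exceeds the
    configured quantile of the cohort distribution (median split by default).
    """
    if abs(clinical_effect) > 1.0:
        raise ValidationError("clinical_effect must satisfy |effect| <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.asarray(latent, dtype=float)
    eta = rng.standard_normal(len(L))
    improvement = clinical_effect * L + math.sqrt(1.0 - clinical_effect**2) * eta
    threshold = np.quantile(improvement, responder_quantile)
    responder = (improvement > threshold).astype(int)
    return pd.DataFrame(
        {"improvement": improvement, "responder": responder},
        index=latent.index if isinstance(latent, pd.Series) else None,
    )


def _module_expression(
    latent: np.ndarray,
    loadings: np.ndarray,
    noise_sd: float,
    confounds: pd.DataFrame,
    confound_effects: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n, p = len(latent), len(loadings)
    base = rng.normal(8.0, 1.0, size=p)  # per-gene baseline intensity
    noise = rng.normal(0.0, noise_sd, size=(p, n))
    X = base[:, None] + loadings[:, None] * latent[None, :] + noise
    X += confound_effects @ confounds.to_numpy(float).T
    return X


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full discovery cohort (expression, genotypes, covariates, truth)."""
    rng = np.random.default_rng(config.seed)
    coords, snp_meta = _snp_panel(config, rng)
    geno = simulate_genotypes(config.n_samples, snp_meta, rng)
    samples = list(geno.sample_ids)

    causal_ids = list(snp_meta.index[: config.n_causal_snps])
    betas = np.full(config.n_causal_snps, config.causal_beta, dtype=float)
    latent, genetic_var = _latent_factor(geno, causal_ids, betas, rng)

    p = config.n_module_genes
    loadings = rng.uniform(config.loading_range[0], config.loading_range[1], size=p)
    loadings[0] = config.loading_range[1]  # seed-gene analogue loads strongly
    noise_sd = solve_module_noise_sd(loadings, config.pc1_target)

    confounds = _draw_confounds(config.confound_spec, config.n_samples, rng)
    confounds.index = samples
    n_genes = p + config.n_background_genes
    eff_ranges = [spec[2] for spec in config.confound_spec]
    confound_effects = np.column_stack(
        [rng.uniform(lo, hi, size=n_genes) for (lo, hi) in eff_ranges]
    )

    Xmod = _module_expression(
        latent, loadings, noise_sd, confounds, confound_effects[:p], rng
    )
    nb = config.n_background_genes
    Xbg = rng.normal(8.0, 1.0, size=nb)[:, None] + rng.normal(
        0.0, 1.0, size=(nb, config.n_samples)
    )
    Xbg += confound_effects[p:] @ confounds.to_numpy(float).T

    gene_ids = list(coords.index)
    values = pd.DataFrame(np.vstack([Xmod, Xbg]), index=gene_ids, columns=samples)
    quality = pd.Series(
        rng.uniform(config.quality_range[0], config.quality_range[1], size=config.n_samples),
        index=samples,
        name="quality",
    )
    expr = ExpressionMatrix(values, quality)
    latent_s = pd.Series(latent, index=samples, name="latent")
    phen = simulate_clinical_outcomes(
        latent_s, config.clinical_effect, config.responder_quantile, rng
    )

    truth = CohortTruth(
        latent=latent_s,
        module_gene_ids=gene_ids[:p],
        seed_gene_id=gene_ids[0],
        loadings=pd.Series(loadings, index=gene_ids[:p]),
        causal_snp_ids=causal_ids,
        causal_betas=pd.Series(betas, index=causal_ids),
        noise_sd=noise_sd,
        genetic_variance_share=genetic_var,
        expected_pc1_fraction=_pc1_fraction(loadings, noise_sd),
        expected_me_latent_cor2=_expected_me_latent_cor2(loadings, noise_sd),
    )
    cohort = SyntheticCohort(
        expression=expr,
        genotypes=geno,
        covariates=CovariateTable(confounds),
        truth=truth,
        phenotypes=phen,
        config=config,
    )
    cohort.gene_coords = coords  # type: ignore[attr-defined]
    return cohort


def simulate_replication_cohort(
    discovery: SyntheticCohort,
    n_samples: int = 50,
    seed: int = 1,
    target_pci_r2: float = 0.15,
    probe_dropout: int | None = None,
    n_background_genes: int = 15,
    quality_range: tuple[float, float] = (4.5, 9.0),
) -> SyntheticCohort:
    """Fresh samples from the discovery generative process, degraded on purpose.

    The SNP panel, allele orientation and gene loadings are reused; the
    causal effect sizes are rescaled so the population R^2 between the
    frozen-weight polygenic score and the recomputed eigengene is
    ``target_pci_r2``; ``probe_dropout`` module genes are absent from the
    expression matrix and quality scores are drawn lower, mimicking an
    independent cohort with partial probe overlap and degraded RNA.
    """
    cfg = discovery.config or CohortConfig()
    dropout = cfg.probe_dropout if probe_dropout is None else probe_dropout
    rng = np.random.default_rng(seed)
    truth_d = discovery.truth

    snp_meta = discovery.genotypes.meta.copy()
    geno = simulate_genotypes(n_samples, snp_meta, rng)
    samples = [f"R{i + 1:04d}" for i in range(n_samples)]
    geno.dosages.index = pd.Index(samples)

    causal_ids = truth_d.causal_snp_ids
    mafs = snp_meta.loc[causal_ids, "maf"].to_numpy(float)
    # rescale betas so genetic share of L times ME-L cor^2 hits the R^2 target
    target_share = min(0.95, target_pci_r2 / truth_d.expected_me_latent_cor2)
    base = truth_d.causal_betas.to_numpy(float)
    base_share = float(np.sum(base**2 * 2 * mafs * (1 - mafs)))
    betas = base * math.sqrt(target_share / base_share)
    latent, genetic_var = _latent_factor(geno, causal_ids, betas, rng)

    keep = truth_d.module_gene_ids[: len(truth_d.module_gene_ids) - dropout]
    loadings = truth_d.loadings.loc[keep].to_numpy(float)

    confounds = _draw_confounds(cfg.confound_spec, n_samples, rng)
    confounds.index = samples
    eff_ranges = [spec[2] for spec in cfg.confound_spec]
    n_genes = len(keep) + n_background_genes
    confound_effects = np.column_stack(
        [rng.uniform(lo, hi, size=n_genes) for (lo, hi) in eff_ranges]
    )
    Xmod = _module_expression(
        latent, loadings, truth_d.noise_sd, confounds, confound_effects[: len(keep)], rng
    )
    Xbg = rng.normal(8.0, 1.0, size=n_background_genes)[:, None] + rng.normal(
        0.0, 1.0, size=(n_background_genes, n_samples)
    )
    Xbg += confound_effects[len(keep):] @ confounds.to_numpy(float).T
    bg_ids = [f"RBG{i + 1:04d}" for i in range(n_background_genes)]
    values = pd.DataFrame(np.vstack([Xmod, Xbg]), index=list(keep) + bg_ids, columns=samples)
    quality = pd.Series(
        rng.uniform(quality_range[0], quality_range[1], size=n_samples),
        index=samples,
        name="quality",
    )
    latent_s = pd.Series(latent, index=samples, name="latent")
    truth = CohortTruth(
        latent=latent_s,
        module_gene_ids=list(keep),
        seed_gene_id=truth_d.seed_gene_id,
        loadings=pd.Series(loadings, index=list(keep)),
        causal_snp_ids=list(causal_ids),
        causal_betas=pd.Series(betas, index=list(causal_ids)),
        noise_sd=truth_d.noise_sd,
        genetic_variance_share=genetic_var,
        expected_pc1_fraction=_pc1_fraction(loadings, truth_d.noise_sd),
        expected_me_latent_cor2=_expected_me_latent_cor2(loadings, truth_d.noise_sd),
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(values, quality),
        genotypes=geno,
        covariates=CovariateTable(confounds),
        truth=truth,
        phenotypes=None,
        config=cfg,
    )


def simulate_clinical_cohort(
    discovery: SyntheticCohort,
    n_samples: int = 87,
    clinical_effect: float | None = None,
    responder_quantile: float | None = None,
    seed: int = 2,
) -> SyntheticCohort:
    """Genotyped clinical cohort with improvement scores tied to the latent factor.

    Only genotypes and phenotypes are produced (no expression): the clinical
    samples are scored with frozen PCI weights and associated with treatment
    improvement, mirroring a pharmacogenetic cohort without brain tissue.
    """
    cfg = discovery.config or CohortConfig()
    eff = cfg.clinical_effect if clinical_effect is None else clinical_effect
    rq = cfg.responder_quantile if responder_quantile is None else responder_quantile
    rng = np.random.default_rng(seed)
    truth_d = discovery.truth
    geno = simulate_genotypes(n_samples, discovery.genotypes.meta.copy(), rng)
    samples = [f"C{i + 1:04d}" for i in range(n_samples)]
    geno.dosages.index = pd.Index(samples)
    betas = truth_d.causal_betas.to_numpy(float)
    latent, genetic_var = _latent_factor(geno, truth_d.causal_snp_ids, betas, rng)
    latent_s = pd.Series(latent, index=samples, name="latent")
    phen = simulate_clinical_outcomes(latent_s, eff, rq, rng)
    confounds = _draw_confounds(cfg.confound_spec, n_samples, rng)
    confounds.index = samples
    truth = CohortTruth(
        latent=latent_s,
        module_gene_ids=list(truth_d.module_gene_ids),
        seed_gene_id=truth_d.seed_gene_id,
        loadings=truth_d.loadings,
        causal_snp_ids=list(truth_d.causal_snp_ids),
        causal_betas=truth_d.causal_betas,
        noise_sd=truth_d.noise_sd,
        genetic_variance_share=genetic_var,
        expected_pc1_fraction=truth_d.expected_pc1_fraction,
        expected_me_latent_cor2=truth_d.expected_me_latent_cor2,
    )
    return SyntheticCohort(
        expression=None,  # type: ignore[arg-type]
        genotypes=geno,
        covariates=CovariateTable(confounds),
        truth=truth,
        phenotypes=phen,
        config=cfg,
    )
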