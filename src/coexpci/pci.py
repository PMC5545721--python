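"""Co-eQTL screening and the Polygenic Co-expression Index (PCI).

A co-eQTL is a variant associated with the co-expression of a whole gene
set — operationally, with the module eigengene (ME) — rather than with a
single transcript. The screen regresses the ME on additive minor-allele
dosage per SNP. Independent SNPs (greedy LD pruning by p-value) passing a
selection rule are combined into the PCI: each genotype of each selected
SNP receives a weight equal to the mean training ME in that genotype group
minus the grand mean, and an individual's PCI is the sum of the weights of
their genotypes. Greater PCI predicts greater module co-expression.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, ValidationError
from .network import Eigengene, module_eigengene

__all__ = [
    "SelectionConfig",
    "PciModel",
    "CrossValidationResult",
    "ReplicationReport",
    "snps_in_gene_windows",
    "coeqtl_scan",
    "bonferroni",
    "ld_prune",
    "select_snps",
    "fit_pci",
    "score_pci",
    "crossvalidate_pci",
    "replicate_pci",
]

log = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """SNP selection rule for the PCI.

    ``method`` is ``"threshold"`` (LD-prune then keep p < alpha, strict) or
    ``"plateau"`` (add pruned SNPs in ascending-p order until the training
    R^2 gain stays below ``plateau_eps`` for two consecutive additions).
    """

    method: str = "threshold"
    alpha: float = 0.005
    r2_max: float = 0.2
    plateau_eps: float = 0.005
    min_group: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("threshold", "plateau"):
            raise ValidationError(f"unknown selection method {self.method!r}")


@dataclass
class PciModel:
    """Fitted PCI scoring function: per-SNP, per-genotype weights.

    ``weights`` maps SNP id -> (w0, w1, w2) for minor-allele doses 0/1/2;
    merged genotype groups share a weight. ``grand_mean`` is the training
    ME mean removed from every group mean.
    """

    snp_ids: list[str]
    weights: dict[str, tuple[float, float, float]]
    grand_mean: float
    training_r2: float
    minor_alleles: dict[str, str] = field(default_factory=dict)
    selection: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["schema_version"] = 1
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PciModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload.pop("schema_version", None)
        payload["weights"] = {k: tuple(v) for k, v in payload["weights"].items()}
        return cls(**payload)


def _norm_chrom(c) -> str:
    s = str(c).strip()
    low = s.lower()
    if low.startswith("chr"):
        return s[3:]
    return s


def snps_in_gene_windows(
    snp_meta: pd.DataFrame, gene_coords: pd.DataFrame, window_bp: int = 100_000
) -> tuple[list[str], pd.DataFrame]:
    """SNPs falling within +/-``window_bp`` of any gene body (closed intervals).

    ``snp_meta`` is indexed by SNP id with ``chrom``/``pos``; ``gene_coords``
    is indexed by gene id with ``chrom``/``start``/``end`` (1-based closed).
    Returns the retained SNP ids (input order) and a SNP->gene mapping table.
    ``chr``-prefixed chromosome names are normalized with a logged note.
    """
    gch = gene_coords["chrom"].map(_norm_chrom)
    sch = snp_meta["chrom"].map(_norm_chrom)
    if (gene_coords["chrom"].astype(str) != gch).any() or (
        snp_meta["chrom"].astype(str) != sch
    ).any():
        log.info("normalized 'chr' prefixes in chromosome names")

    trees: dict[str, IntervalTree] = {}
    for gene, row in gene_coords.assign(chrom=gch).iterrows():
        lo = int(row["start"]) - window_bp
        hi = int(row["end"]) + window_bp
        # IntervalTree is half-open; +1 makes the closed upper bound inclusive
        trees.setdefault(row["chrom"], IntervalTree()).addi(lo, hi + 1, gene)

    kept, rows = [], []
    for snp, row in snp_meta.assign(chrom=sch).iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        hits = tree[int(row["pos"])]
        if hits:
            kept.append(snp)
            for h in sorted(hits, key=lambda iv: iv.data):
                rows.append((snp, h.data))
    mapping = pd.DataFrame(rows, columns=["snp", "gene"])
    return kept, mapping


def _ols_slope_test(
    y: np.ndarray, x: np.ndarray, covars: np.ndarray | None
) -> tuple[float, float, float, int]:
    """Slope, t and two-sided p for y ~ intercept + x (+ covariates)."""
    n = len(y)
    cols = [np.ones(n), x]
    if covars is not None:
        cols.extend(np.asarray(covars, float).T)
    X = np.column_stack(cols)
    df = n - X.shape[1]
    if df < 1:
        raise ValidationError("not enough residual degrees of freedom")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValidationError("rank-deficient design in co-eQTL regression")
    resid = y - X @ beta
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[1, 1])
    slope = float(beta[1])
    if se == 0:
        t = math.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return slope, float(t), float(p), df


def coeqtl_scan(
    me: Eigengene | pd.Series,
    geno: GenotypeMatrix,
    covars: pd.DataFrame | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-SNP OLS of the ME on additive dosage; two-sided t-test on the slope.

    Untestable SNPs (monomorphic after missing-genotype removal, or fewer
    than ``min_n`` called samples) are flagged in the ``status`` column
    rather than dropped. Returns a frame indexed by SNP id with columns
    ``slope``, ``t``, ``p``, ``n``, ``n0``, ``n1``, ``n2``, ``status``.
    """
    scores = me.scores if isinstance(me, Eigengene) else me
    scores = scores.reindex(geno.sample_ids)
    if scores.isna().any():
        raise ValidationError("ME scores missing for some genotyped samples")
    y_all = scores.to_numpy(float)
    C_all = None
    if covars is not None:
        C_all = covars.reindex(geno.sample_ids).to_numpy(float)
        if np.isnan(C_all).any():
            raise ValidationError("covariates missing for some genotyped samples")

    rows = []
    D = geno.dosages.to_numpy(float)
    for j, snp in enumerate(geno.snp_ids):
        x = D[:, j]
        mask = ~np.isnan(x)
        n = int(mask.sum())
        counts = [int(np.sum(x[mask] == d)) for d in (0.0, 1.0, 2.0)]
        if n < min_n:
            rows.append((snp, np.nan, np.nan, np.nan, n, *counts, "low_n"))
            continue
        if len(np.unique(x[mask])) < 2:
            rows.append((snp, np.nan, np.nan, np.nan, n, *counts, "untestable"))
            continue
        C = C_all[mask] if C_all is not None else None
        slope, t, p, _ = _ols_slope_test(y_all[mask], x[mask], C)
        rows.append((snp, slope, t, p, n, *counts, "ok"))
    out = pd.DataFrame(
        rows, columns=["snp", "slope", "t", "p", "n", "n0", "n1", "n2", "status"]
    ).set_index("snp")
    return out


def bonferroni(pvalues, n_tests: int):
    """min(1, p * n_tests); the family size may exceed the number supplied."""
    p = np.asarray(pvalues, dtype=float)
    if n_tests < p.size:
        raise ValidationError("n_tests must cover the whole family of tests")
    out = np.minimum(1.0, p * n_tests)
    return float(out) if np.isscalar(pvalues) or out.ndim == 0 else out


def ld_prune(geno: GenotypeMatrix, pvalues: pd.Series, r2_max: float) -> list[str]:
    """Greedy p-ordered pruning: accept a SNP iff dosage r^2 with every
    accepted SNP is below ``r2_max``. Ties in p break lexicographically."""
    missing = geno.snp_ids.difference(pvalues.index)
    if len(missing):
        raise ValidationError(f"p-values missing for SNPs: {list(missing)[:5]}")
    order = sorted(geno.snp_ids, key=lambda s: (pvalues[s], s))
    D = geno.dosages
    accepted: list[str] = []
    for snp in order:
        if not np.isfinite(pvalues[snp]):
            continue
        ok = True
        x = D[snp]
        for kept in accepted:
            r = x.corr(D[kept])  # pairwise-complete
            if np.isfinite(r) and r**2 >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(snp)
    return accepted


def select_snps(
    coeqtl: pd.DataFrame,
    geno: GenotypeMatrix,
    config: SelectionConfig,
    me: Eigengene | pd.Series | None = None,
) -> tuple[list[str], pd.DataFrame | None]:
    """Select independent SNPs for the PCI.

    Fixed-threshold: LD-prune then keep p < alpha (strict). Plateau: add
    pruned SNPs in ascending-p order, refitting the PCI training R^2 at
    each step, and stop once the incremental R^2 stays below
    ``plateau_eps`` for two consecutive additions (``me`` required).
    Returns (selected ids, R^2-vs-k trace or None).
    """
    testable = coeqtl[coeqtl["status"] == "ok"]
    pruned = ld_prune(geno.subset_snps(list(testable.index)), testable["p"], config.r2_max)
    pruned = sorted(pruned, key=lambda s: (testable.loc[s, "p"], s))

    if config.method == "threshold":
        selected = [s for s in pruned if testable.loc[s, "p"] < config.alpha]
        if not selected:
            raise ValidationError("empty model: no SNP passed the selection threshold")
        return selected, None

    if me is None:
        raise ValidationError("plateau selection requires the training ME")
    scores = me.scores if isinstance(me, Eigengene) else me
    n = int(scores.reindex(geno.sample_ids).notna().sum())
    trace_rows = []
    best_k = 0
    below = 0
    prev_adj = 0.0
    for k in range(1, len(pruned) + 1):
        model = fit_pci(me, geno, pruned[:k], min_group=config.min_group)
        r2 = model.training_r2
        # adjust for the group-mean parameters each SNP contributes (~2 per
        # SNP), otherwise every null SNP adds a mechanical ~2/n gain
        n_params = sum(len(set(model.weights[s])) - 1 for s in model.snp_ids)
        dof = max(n - 1 - n_params, 1)
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        gain = r2_adj - prev_adj
        trace_rows.append((k, pruned[k - 1], r2, r2_adj, gain))
        if gain < config.plateau_eps:
            below += 1
            if below >= 2:
                break
        else:
            below = 0
            best_k = k
        prev_adj = r2_adj
    if best_k == 0:
        raise ValidationError("empty model: no SNP improved the fit above plateau_eps")
    trace = pd.DataFrame(trace_rows, columns=["k", "snp", "r2", "r2_adj", "gain"])
    return pruned[:best_k], trace


def _group_means(y: np.ndarray, dose: np.ndarray, min_group: int):
    """Genotype-group ME means with small groups merged toward the heterozygote.

    Returns per-dose means (w0, w1, w2) or None if fewer than two groups of
    size >= min_group remain after merging.
    """
    groups = {d: y[dose == d] for d in (0.0, 1.0, 2.0)}
    merged = {0.0: [0.0], 1.0: [1.0], 2.0: [2.0]}
    for d in (2.0, 0.0):  # merge homozygote into heterozygote if tiny
        if 0 < len(groups[d]) < min_group or (len(groups[d]) == 0 and False):
            merged[1.0].append(d)
            merged[d] = None  # type: ignore[assignment]
        elif len(groups[d]) == 0:
            merged[d] = None  # type: ignore[assignment]
    means = {}
    for d, members in merged.items():
        if members is None:
            continue
        vals = np.concatenate([groups[m] for m in members])
        if len(vals) == 0:
            merged[d] = None  # type: ignore[assignment]
            continue
        means[d] = float(vals.mean())
    live = [d for d in means if len(np.concatenate([groups[m] for m in merged[d]])) >= min_group]
    if len(live) < 2:
        return None
    # merged doses inherit the heterozygote-pooled mean
    out = {}
    for d in (0.0, 1.0, 2.0):
        if merged[d] is None:
            out[d] = means.get(1.0, np.nan)
        else:
            out[d] = means[d]
    if any(not np.isfinite(v) for v in out.values()):
        return None
    return out[0.0], out[1.0], out[2.0]


def fit_pci(
    me: Eigengene | pd.Series,
    geno: GenotypeMatrix,
    selected_ids,
    min_group: int = 5,
) -> PciModel:
    """Fit per-genotype weights: group mean of the training ME minus grand mean.

    Genotype groups smaller than ``min_group`` are merged into the
    heterozygote group before computing means; SNPs collapsing to a single
    group are dropped with a warning. The training R^2 of OLS ME ~ PCI is
    stored on the model.
    """
    selected_ids = list(selected_ids)
    if not selected_ids:
        raise ValidationError("cannot fit PCI on an empty SNP set")
    missing = set(selected_ids) - set(geno.snp_ids)
    if missing:
        raise ValidationError(f"selected SNPs absent from genotypes: {sorted(missing)}")
    scores = me.scores if isinstance(me, Eigengene) else me
    scores = scores.reindex(geno.sample_ids)
    y = scores.to_numpy(float)
    grand_mean = float(np.nanmean(y))

    weights: dict[str, tuple[float, float, float]] = {}
    minor: dict[str, str] = {}
    for snp in selected_ids:
        x = geno.dosages[snp].to_numpy(float)
        mask = ~np.isnan(x) & ~np.isnan(y)
        gm = _group_means(y[mask], x[mask], min_group)
        if gm is None:
            log.warning("SNP %s collapsed to a single genotype group; dropped", snp)
            continue
        weights[snp] = tuple(float(v - grand_mean) for v in gm)  # type: ignore[assignment]
        if "minor" in geno.meta.columns:
            minor[snp] = str(geno.meta.loc[snp, "minor"])
    if not weights:
        raise ValidationError("empty model: every selected SNP collapsed to one group")

    model = PciModel(
        snp_ids=list(weights),
        weights=weights,
        grand_mean=grand_mean,
        training_r2=0.0,
        minor_alleles=minor,
    )
    pci = score_pci(model, geno)
    valid = ~np.isnan(y)
    if np.std(pci.to_numpy(float)[valid]) == 0 or np.std(y[valid]) == 0:
        model.training_r2 = 0.0
    else:
        r = np.corrcoef(pci.to_numpy(float)[valid], y[valid])[0, 1]
        model.training_r2 = float(r**2)
    return model


def score_pci(model: PciModel, geno: GenotypeMatrix, missing_warn: float = 0.5) -> pd.Series:
    """Per-sample PCI: sum of genotype weights over model SNPs.

    Missing genotypes contribute 0 (the centered-null contribution).
    Samples missing more than ``missing_warn`` of the model SNPs are
    flagged via ``result.attrs['flagged_samples']``. A SNP whose recorded
    minor allele disagrees with the cohort's is dose-flipped with a warning.
    """
    absent = [s for s in model.snp_ids if s not in geno.snp_ids]
    if absent:
        raise ValidationError(f"model SNPs absent from cohort: {absent}")
    total = np.zeros(geno.n_samples)
    n_missing = np.zeros(geno.n_samples)
    for snp in model.snp_ids:
        x = geno.dosages[snp].to_numpy(float)
        if (
            snp in model.minor_alleles
            and "minor" in geno.meta.columns
            and str(geno.meta.loc[snp, "minor"]) != model.minor_alleles[snp]
        ):
            log.warning("minor allele mismatch for %s; flipping dosage", snp)
            x = 2.0 - x
        w = np.asarray(model.weights[snp], dtype=float)
        miss = np.isnan(x)
        contrib = np.where(miss, 0.0, w[np.nan_to_num(x, nan=0.0).astype(int)])
        total += contrib
        n_missing += miss
    result = pd.Series(total, index=geno.sample_ids, name="PCI")
    flagged = list(geno.sample_ids[n_missing > missing_warn * len(model.snp_ids)])
    result.attrs["flagged_samples"] = flagged
    return result


@dataclass
class CrossValidationResult:
    pooled_r: float
    pooled_p_one_tailed: float
    fold_r: list[float]
    n_folds: int
    n_failed_folds: int
    pooled_scores: pd.Series
    fold_snp_sets: list[list[str]]


def _one_tailed_p(r: float, n: int) -> float:
    if n < 3 or not np.isfinite(r):
        return float("nan")
    r = min(max(r, -0.999999999), 0.999999999)
    t = r * math.sqrt((n - 2) / (1.0 - r**2))
    return float(stats.t.sf(t, n - 2))


def crossvalidate_pci(
    me: Eigengene | pd.Series,
    geno: GenotypeMatrix,
    selection: SelectionConfig,
    k_folds: int = 5,
    seed: int = 0,
    reselect: bool = True,
    covars: pd.DataFrame | None = None,
) -> CrossValidationResult:
    """K-fold cross-validation of the PCI.

    Per fold, SNPs are re-selected (``reselect=True``, the stricter
    default: the co-eQTL scan, pruning and thresholding all run on the
    training portion only) or only re-weighted on a fixed SNP set; held-out
    samples are scored with the fold's frozen weights. Reports the Pearson
    r between pooled out-of-fold PCI and the ME. Folds with an empty model
    are flagged, excluded from pooling and counted.
    """
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    scores = me.scores if isinstance(me, Eigengene) else me
    scores = scores.reindex(geno.sample_ids)
    n = len(scores)
    if n < 2 * k_folds:
        raise ValidationError("need at least 2 samples per fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)

    fixed_ids: list[str] | None = None
    if not reselect:
        scan = coeqtl_scan(scores, geno, covars)
        fixed_ids, _ = select_snps(scan, geno, selection, me=scores)

    pooled = pd.Series(np.nan, index=geno.sample_ids, dtype=float)
    fold_r: list[float] = []
    fold_sets: list[list[str]] = []
    failed = 0
    for test_idx in folds:
        test_samples = geno.sample_ids[np.sort(test_idx)]
        train_samples = geno.sample_ids.difference(test_samples, sort=False)
        g_tr = geno.subset_samples(train_samples)
        g_te = geno.subset_samples(test_samples)
        y_tr = scores.loc[train_samples]
        try:
            if reselect:
                scan = coeqtl_scan(y_tr, g_tr, covars.loc[train_samples] if covars is not None else None)
                ids, _ = select_snps(scan, g_tr, selection, me=y_tr)
            else:
                ids = fixed_ids  # type: ignore[assignment]
            model = fit_pci(y_tr, g_tr, ids, min_group=selection.min_group)
        except ValidationError as exc:
            log.warning("fold failed (%s); excluded from pooling", exc)
            failed += 1
            fold_r.append(float("nan"))
            fold_sets.append([])
            continue
        s_te = score_pci(model, g_te)
        pooled.loc[test_samples] = s_te
        y_te = scores.loc[test_samples].to_numpy(float)
        if np.std(s_te) > 0 and np.std(y_te) > 0:
            fold_r.append(float(np.corrcoef(s_te, y_te)[0, 1]))
        else:
            fold_r.append(float("nan"))
        fold_sets.append(list(model.snp_ids))

    valid = pooled.notna()
    if valid.sum() >= 3 and pooled[valid].std() > 0:
        r = float(np.corrcoef(pooled[valid], scores[valid])[0, 1])
    else:
        r = float("nan")
    return CrossValidationResult(
        pooled_r=r,
        pooled_p_one_tailed=_one_tailed_p(r, int(valid.sum())),
        fold_r=fold_r,
        n_folds=k_folds,
        n_failed_folds=failed,
        pooled_scores=pooled,
        fold_snp_sets=fold_sets,
    )


@dataclass
class ReplicationReport:
    r: float
    p_one_tailed: float
    n: int
    n_module_genes_used: int
    explained_variance_fraction: float
    strata: dict


def replicate_pci(
    model: PciModel,
    replication_expr: ExpressionMatrix,
    module_member_ids,
    seed_gene_id: str | None,
    replication_geno: GenotypeMatrix,
    min_member_fraction: float = 0.5,
    quality_threshold: float = 6.0,
) -> ReplicationReport:
    """Frozen-weights replication in an independent cohort.

    The ME is recomputed by PCA on the intersection of module genes present
    in the replication expression (sign re-oriented by the seed gene or the
    mean-member rule); individuals are scored with the *training* weights,
    and the Pearson correlation between PCI and recomputed ME is reported
    with a one-tailed p for r > 0, overall and stratified by sample quality
    (all vs quality > ``quality_threshold``).
    """
    present = [g for g in module_member_ids if g in replication_expr.gene_ids]
    frac = len(present) / max(len(list(module_member_ids)), 1)
    if frac < min_member_fraction:
        raise ValidationError(
            f"only {frac:.0%} of module genes present in replication cohort "
            f"(floor {min_member_fraction:.0%})"
        )
    common = replication_expr.sample_ids.intersection(replication_geno.sample_ids)
    expr = replication_expr.subset_samples(common)
    geno = replication_geno.subset_samples(common)
    eig = module_eigengene(expr, present, seed_gene_id)
    pci = score_pci(model, geno)

    def _stratum(mask: np.ndarray) -> dict:
        nn = int(mask.sum())
        if nn < 3:
            return {"r": float("nan"), "p_one_tailed": float("nan"), "n": nn}
        a = pci.to_numpy(float)[mask]
        b = eig.scores.to_numpy(float)[mask]
        if np.std(a) == 0 or np.std(b) == 0:
            return {"r": float("nan"), "p_one_tailed": float("nan"), "n": nn}
        r = float(np.corrcoef(a, b)[0, 1])
        return {"r": r, "p_one_tailed": _one_tailed_p(r, nn), "n": nn}

    all_mask = np.ones(len(common), dtype=bool)
    strata = {"all": _stratum(all_mask)}
    if expr.quality is not None:
        strata[f"quality>{quality_threshold:g}"] = _stratum(
            expr.quality.to_numpy(float) > quality_threshold
        )
    top = strata["all"]
    return ReplicationReport(
        r=top["r"],
        p_one_tailed=top["p_one_tailed"],
        n=top["n"],
        n_module_genes_used=len(present),
        explained_variance_fraction=eig.explained_variance_fraction,
        strata=strata,
    )
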