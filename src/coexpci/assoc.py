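"""Phenotype associations for the PCI.

Covers the downstream statistics of the pipeline: linear (optionally
robust) regression of a phenotype on the PCI with covariates, a two-level
repeated-measures interaction test implemented exactly through difference
scores, hypergeometric gene-set enrichment, Spearman rank association,
ROC/AUC treatment-response prediction with a Mann-Whitney p, and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln, logsumexp

from .containers import ValidationError

__all__ = [
    "AssocResult",
    "linear_assoc",
    "rm_interaction_test",
    "hypergeom_enrichment",
    "spearman_assoc",
    "roc_auc",
    "bh_fdr",
]

log = logging.getLogger(__name__)


@dataclass
class AssocResult:
    """One association statistic with its provenance recorded."""

    estimate: float
    statistic: float
    p: float
    sidedness: str  # "one" | "two"
    n: int
    df: float | None = None
    covariates: list[str] = field(default_factory=list)
    correction: str = "none"
    q: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sidedness not in ("one", "two"):
            raise ValidationError("sidedness must be 'one' or 'two'")


def _sided_p(t: float, df: float, sidedness: str) -> float:
    if sidedness == "two":
        return float(2.0 * stats.t.sf(abs(t), df))
    return float(stats.t.sf(t, df))  # one-tailed, positive direction


def _design(pci: np.ndarray, covars: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(pci)), np.asarray(pci, float)]
    names: list[str] = []
    if covars is not None:
        for c in covars.columns:
            cols.append(covars[c].to_numpy(float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design in linear association")
    return X, names


def linear_assoc(
    y,
    pci,
    covars: pd.DataFrame | None = None,
    robust: bool = False,
    sidedness: str = "two",
) -> AssocResult:
    """Regression of a phenotype on intercept + PCI (+ covariates).

    ``robust=True`` switches to Huber M-estimation (tuning constant 1.345,
    IRLS to 1e-8 or 50 iterations); the reported test is on the PCI
    coefficient with the requested sidedness.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(np.asarray(pci, float), covars)
    n = len(y)
    df = n - X.shape[1]
    if robust:
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            conv="coefs", tol=1e-8, maxiter=50
        )
    else:
        fit = sm.OLS(y, X).fit()
    est = float(fit.params[1])
    se = float(fit.bse[1])
    resid_scale = float(np.max(np.abs(y - X @ fit.params)))
    y_scale = max(1.0, float(np.max(np.abs(y))))
    if se == 0 or not np.isfinite(se) or resid_scale <= 1e-10 * y_scale:
        # numerically perfect fit: the t statistic is degenerate
        exact_zero = abs(est) <= 1e-10 * y_scale
        est = 0.0 if exact_zero else est
        tval = 0.0 if exact_zero else math.inf * np.sign(est)
        p = (1.0 if exact_zero else 0.0) if sidedness == "two" else (
            0.0 if est > 0 else 1.0
        )
    else:
        tval = est / se
        p = _sided_p(tval, df, sidedness)
    return AssocResult(
        estimate=est, statistic=tval, p=p, sidedness=sidedness, n=n, df=df, covariates=names
    )


def rm_interaction_test(
    y_load1,
    y_load2,
    pci,
    covars: pd.DataFrame | None = None,
    family_alpha: float = 0.025,
) -> AssocResult:
    """LOAD x PCI interaction for a two-level within-subject factor.

    With exactly two within-subject levels the repeated-measures ANCOVA
    interaction F equals t^2 from the OLS regression of the per-subject
    difference (load2 - load1) on intercept + PCI + covariates, so the
    test is implemented on difference scores. Per-load post-hoc
    regressions are attached under ``extra``; ``family_alpha`` (the
    Bonferroni threshold over the measure family) is reported as metadata,
    not used for rejection.
    """
    y1 = np.asarray(y_load1, dtype=float)
    y2 = np.asarray(y_load2, dtype=float)
    x = np.asarray(pci, dtype=float)
    mask = ~(np.isnan(y1) | np.isnan(y2) | np.isnan(x))
    if covars is not None:
        mask &= ~covars.isna().any(axis=1).to_numpy()
    dropped = int((~mask).sum())
    if dropped:
        log.info("dropped %d samples with missing paired values", dropped)
    cv = covars.loc[mask] if covars is not None else None
    res = linear_assoc(y2[mask] - y1[mask], x[mask], cv, sidedness="two")
    F = res.statistic**2
    post = {
        "load1": linear_assoc(y1[mask], x[mask], cv, sidedness="two"),
        "load2": linear_assoc(y2[mask], x[mask], cv, sidedness="two"),
    }
    return AssocResult(
        estimate=res.estimate,
        statistic=float(F),
        p=res.p,
        sidedness="two",
        n=res.n,
        df=res.df,
        covariates=res.covariates,
        extra={"post_hoc": post, "family_alpha": family_alpha, "dropped": dropped},
    )


def hypergeom_enrichment(
    module_size: int, module_hits: int, background_size: int, background_hits: int
) -> float:
    """Upper-tail hypergeometric enrichment p-value, exact in log-space.

    P(X >= module_hits) for X ~ Hypergeom(N=background_size,
    K=background_hits, n=module_size), summed over the attainable tail
    with log-binomials for numerical stability.
    """
    N, K, n, k = background_size, background_hits, module_size, module_hits
    if not (0 <= k <= min(n, K)) or N < n or K > N:
        raise ValidationError(
            f"impossible counts: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0

    def log_comb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = log_comb(N, n)
    terms = [
        log_comb(K, j) + log_comb(N - K, n - j) - denom
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    ]
    if not terms:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(terms))))


def spearman_assoc(improvement, pci, sidedness: str = "two") -> AssocResult:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t approximation rho*sqrt((n-2)/(1-rho^2)) with
    n-2 degrees of freedom; one-tailed tests are for rho > 0.
    """
    a = np.asarray(improvement, dtype=float)
    b = np.asarray(pci, dtype=float)
    if len(a) < 5:
        raise ValidationError("Spearman association requires n >= 5")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("constant vector in Spearman association")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    n = len(a)
    df = n - 2
    if abs(rho) >= 1.0:
        t = math.inf * np.sign(rho)
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho**2))
        p = _sided_p(t, df, sidedness)
    return AssocResult(estimate=rho, statistic=float(t), p=p, sidedness=sidedness, n=n, df=df)


def roc_auc(score, labels) -> AssocResult:
    """ROC AUC with curve points and a one-tailed Mann-Whitney p (AUC > 0.5).

    AUC = (concordant + 0.5 * tied pairs) / (n1 * n0), computed from
    mid-ranks; the p-value uses the tie-corrected normal approximation of
    the Mann-Whitney U statistic without continuity correction.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("labels must contain exactly two classes")
    pos = y == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(s)
    U1 = float(ranks[pos].sum() - n1 * (n1 + 1) / 2.0)
    auc = U1 / (n1 * n0)

    n = n1 + n0
    _, counts = np.unique(s, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        p = 0.5
        z = 0.0
    else:
        z = (U1 - n1 * n0 / 2.0) / math.sqrt(var_u)
        p = float(stats.norm.sf(z))

    # ROC curve over all score thresholds, descending
    order = np.argsort(-s, kind="mergesort")
    ys = pos[order].astype(float)
    ss = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tps = np.cumsum(ys)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})

    return AssocResult(
        estimate=float(auc),
        statistic=float(z),
        p=p,
        sidedness="one",
        n=n,
        extra={"curve": curve, "n_pos": n1, "n_neg": n0, "U": U1},
    )


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up q-values mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
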