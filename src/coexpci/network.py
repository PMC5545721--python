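"""Weighted co-expression network construction and module detection.

The construction follows the classic weighted-network recipe: Pearson
correlation between genes, soft thresholding by a power chosen for
approximate scale-free topology, topological overlap as the similarity,
average-linkage hierarchical clustering on 1 - TOM, and a static cut of the
dendrogram. The module containing a designated seed gene is the object of
interest downstream; its first principal component (module eigengene, ME)
summarizes the module's shared variation, and intramodular connectivity
ranks member genes as hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "NetworkConfig",
    "ModulePartition",
    "Eigengene",
    "select_soft_power",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "seed_module",
    "module_eigengene",
    "intramodular_connectivity",
]

log = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    """Network construction parameters.

    ``cut_height`` is the static dendrogram cut expressed as a fraction of
    the maximum merge height. The defaults (unsigned network, power grid
    1-20 with scale-free R^2 >= 0.8, cut at 0.998, minimum module size 20)
    are conventional choices; all are exposed because the appropriate
    values are data-dependent.
    """

    signed: bool = False
    power_grid: tuple = tuple(range(1, 21))
    scale_free_r2_min: float = 0.8
    cut_height: float = 0.998
    min_module_size: int = 20

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.power_grid):
            raise ValidationError("power_grid entries must be >= 1")
        if not (0.0 < self.cut_height < 1.0):
            raise ValidationError("cut_height must lie in (0, 1)")


@dataclass
class ModulePartition:
    """Gene -> module label mapping; label 0 means unassigned (grey)."""

    labels: pd.Series  # index gene id, int labels

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class Eigengene:
    """First principal component of a module's gene-standardized expression."""

    scores: pd.Series  # unit variance, index = sample ids
    explained_variance_fraction: float
    orientation_sign: int
    member_ids: list[str] = field(default_factory=list)


def _correlation(expr: ExpressionMatrix) -> np.ndarray:
    X = expr.values.to_numpy(float)
    sd = X.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValidationError(
            f"zero-variance gene(s): {list(expr.gene_ids[zero][:5])}"
        )
    return np.corrcoef(X)


def adjacency(expr: ExpressionMatrix, power: float, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency with zero diagonal.

    unsigned: ``|cor|^power``; signed: ``((1 + cor)/2)^power``.
    """
    if power < 1:
        raise ValidationError("power must be >= 1")
    cor = _correlation(expr)
    if signed:
        A = ((1.0 + cor) / 2.0) ** power
    else:
        A = np.abs(cor) ** power
    np.fill_diagonal(A, 0.0)
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(A, index=expr.gene_ids, columns=expr.gene_ids)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 of log10(freq) on log10(mean connectivity) over connectivity bins.

    Returns (r2, slope); a positive slope (anti-scale-free) yields r2=0.
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    if k.max() - k.min() <= 1e-9 * max(k.max(), 1.0):
        return 0.0, 0.0  # near-constant connectivity: fit is meaningless
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r**2) if slope < 0 else 0.0
    return r2, float(slope)


def select_soft_power(expr: ExpressionMatrix, config: NetworkConfig) -> int:
    """Smallest grid power reaching the scale-free fit threshold.

    If no power reaches ``scale_free_r2_min``, the power maximizing R^2 is
    returned with a logged warning.
    """
    if expr.n_genes < 20:
        raise ValidationError("need at least 20 genes to assess scale-free topology")
    cor = _correlation(expr)
    base = np.abs(cor) if not config.signed else (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)
    best_power, best_r2 = None, -1.0
    for power in config.power_grid:
        k = (base**power).sum(axis=1)
        r2, _ = _scale_free_r2(k)
        if r2 >= config.scale_free_r2_min:
            return int(power)
        if r2 > best_r2:
            best_power, best_r2 = int(power), r2
    log.warning(
        "no power reached scale-free R^2 >= %.2f; using power %d (R^2=%.3f)",
        config.scale_free_r2_min,
        best_power,
        best_r2,
    )
    return best_power


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j (the shared-neighbor sum excludes u in {i, j} because the
    diagonal of the adjacency is zero), TOM_ii = 1.
    """
    A = adj.to_numpy(float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValidationError("adjacency must be square and symmetric")
    if np.any(np.diag(A) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if A.min() < 0 or A.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    shared = A @ A  # zero diagonal makes this sum over u != i, j plus a_ii terms
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = num / den
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` are relabeled 0 (grey).
    Remaining modules are numbered 1..K by decreasing size, ties broken by
    the smallest member position in the input gene order.
    """
    genes = tom.index
    D = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    max_h = Z[:, 2].max()
    if max_h <= 0:
        raw = np.ones(len(genes), dtype=int)
    else:
        raw = fcluster(Z, t=config.cut_height * max_h, criterion="distance")
    labels = pd.Series(raw, index=genes)

    sizes = labels.value_counts()
    small = sizes[sizes < config.min_module_size].index
    labels[labels.isin(small)] = 0

    # deterministic relabeling: by size desc, then smallest member position
    order = []
    pos = {g: i for i, g in enumerate(genes)}
    for lab in labels.unique():
        if lab == 0:
            continue
        members = labels.index[labels == lab]
        order.append((-len(members), min(pos[g] for g in members), lab))
    remap = {lab: i + 1 for i, (_, _, lab) in enumerate(sorted(order))}
    remap[0] = 0
    return ModulePartition(labels.map(remap).astype(int))


def seed_module(partition: ModulePartition, seed_gene_id: str) -> tuple[int, list[str]]:
    """Module label and member ids of the module containing the seed gene."""
    if seed_gene_id not in partition.labels.index:
        raise ValidationError(f"seed gene {seed_gene_id!r} not present in partition")
    label = int(partition.labels[seed_gene_id])
    if label == 0:
        raise ValidationError(
            f"seed gene {seed_gene_id!r} is unassigned (grey module); no seed module exists"
        )
    return label, partition.members(label)


def module_eigengene(
    expr: ExpressionMatrix, member_ids, seed_gene_id: str | None = None
) -> Eigengene:
    """First PC of the gene-standardized member submatrix, sign-oriented.

    The returned scores have unit variance. Orientation makes the
    correlation with the seed gene's expression non-negative; without a
    seed gene (or if it is absent from the members' cohort) the mean
    correlation with member genes is made non-negative.
    """
    member_ids = list(member_ids)
    if len(member_ids) < 2:
        raise ValidationError("module eigengene needs at least 2 member genes")
    sub = expr.values.loc[member_ids].to_numpy(float)
    sd = sub.std(axis=1)
    if np.any(sd == 0):
        raise ValidationError("module contains zero-variance gene(s)")
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # PCA on samples x genes
    U, S, _ = np.linalg.svd(Z.T, full_matrices=False)
    scores = U[:, 0] * S[0]
    explained = float(S[0] ** 2 / np.sum(S**2))

    sign = 1
    if seed_gene_id is not None and seed_gene_id in expr.gene_ids:
        ref = expr.values.loc[seed_gene_id].to_numpy(float)
        c = np.corrcoef(scores, ref)[0, 1]
        if c < 0:
            sign = -1
    else:
        mean_c = np.mean([np.corrcoef(scores, z)[0, 1] for z in Z])
        if mean_c < 0:
            sign = -1
    scores = sign * scores
    scores = scores / scores.std(ddof=1)
    return Eigengene(
        scores=pd.Series(scores, index=expr.sample_ids, name="ME"),
        explained_variance_fraction=explained,
        orientation_sign=sign,
        member_ids=member_ids,
    )


def intramodular_connectivity(adj: pd.DataFrame, member_ids) -> pd.DataFrame:
    """Within-module connectivity kIN per member gene, ranked descending.

    Ties are broken lexicographically by gene id.
    """
    member_ids = list(member_ids)
    missing = set(member_ids) - set(adj.index)
    if missing:
        raise ValidationError(f"members absent from adjacency: {sorted(missing)[:5]}")
    sub = adj.loc[member_ids, member_ids]
    kin = sub.sum(axis=1)  # diagonal is zero, so this excludes self
    out = pd.DataFrame({"gene": kin.index, "kIN": kin.to_numpy(float)})
    out = out.sort_values(["kIN", "gene"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
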