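"""Core data containers shared across the pipeline.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that every stage of the pipeline agrees on orientation and identifier
semantics:

* expression is genes x samples,
* genotypes are samples x SNPs with dosages counting the minor allele,
* covariates are samples x named numeric columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "CovariateTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Continuous expression values, genes in rows and samples in columns.

    Parameters
    ----------
    values
        genes x samples frame; the index holds gene ids and the columns
        hold sample ids.
    quality
        Optional per-sample quality score (an RNA-integrity analogue) used
        for sample QC and quality-stratified reporting.
    """

    values: pd.DataFrame
    quality: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("expression values must be a DataFrame")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.quality is not None:
            self.quality = pd.Series(self.quality).reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.quality)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        q = self.quality.loc[list(sample_ids)] if self.quality is not None else None
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], q)


_VALID_DOSES = np.array([0.0, 1.0, 2.0])


@dataclass
class GenotypeMatrix:
    """Minor-allele dosages, samples in rows and SNPs in columns.

    ``dosages`` holds floats in {0, 1, 2} with NaN for missing calls;
    ``meta`` is indexed by SNP id with columns ``chrom``, ``pos``,
    ``minor``, ``major`` and ``maf``.
    """

    dosages: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "sample")
        _check_unique(self.dosages.columns, "snp")
        arr = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(arr) | np.isin(arr, _VALID_DOSES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage value {arr[i, j]!r} outside {{0,1,2,NA}} at sample "
                f"{self.dosages.index[i]!r}, snp {self.dosages.columns[j]!r}"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.dosages.columns)
        else:
            missing = self.dosages.columns.difference(self.meta.index)
            if len(missing):
                raise ValidationError(f"snp metadata missing for: {list(missing)[:5]}")
            self.meta = self.meta.loc[self.dosages.columns]

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def empirical_maf(self) -> pd.Series:
        """Minor-allele frequency recomputed from the dosage matrix."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(sample_ids)], self.meta)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        ids = list(snp_ids)
        return GenotypeMatrix(self.dosages.loc[:, ids], self.meta.loc[ids])


@dataclass
class CovariateTable:
    """Numeric covariates per sample (categoricals already expanded).

    Categorical columns are expanded to indicator contrasts dropping the
    first level; constant columns are rejected because they are collinear
    with the intercept added downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        expanded = pd.get_dummies(self.table, drop_first=True, dtype=float)
        non_numeric = [
            c for c in expanded.columns if not np.issubdtype(expanded[c].dtype, np.number)
        ]
        if non_numeric:
            raise ValidationError(f"covariate columns not numeric after expansion: {non_numeric}")
        const = [c for c in expanded.columns if expanded[c].nunique(dropna=True) <= 1]
        if const:
            raise ValidationError(f"constant covariate columns: {const}")
        self.table = expanded

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def aligned_to(self, sample_ids) -> "CovariateTable":
        missing = pd.Index(sample_ids).difference(self.table.index)
        if len(missing):
            raise ValidationError(f"covariates missing for samples: {list(missing)[:5]}")
        out = CovariateTable.__new__(CovariateTable)
        out.table = self.table.loc[list(sample_ids)]
        return out

    def design_matrix(self) -> np.ndarray:
        """Intercept-augmented design matrix; raises on rank deficiency."""
        X = np.column_stack([np.ones(len(self.table)), self.table.to_numpy(float)])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # locate collinear columns by checking rank with each dropped
            collinear = []
            for j, name in enumerate(self.table.columns, start=1):
                Xd = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(Xd) == rank:
                    collinear.append(name)
            raise ValidationError(f"rank-deficient covariate design; collinear columns: {collinear}")
        return X
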