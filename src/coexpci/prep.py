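"""Expression preprocessing: sample QC and confound residualization.

Samples are filtered on a per-sample quality score (an RNA-integrity
analogue, strict ``quality > threshold``) and every gene is then replaced
by the residuals of an ordinary least-squares fit on an intercept plus the
covariate columns, removing linear demographic confounding before network
construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CovariateTable, ExpressionMatrix, ValidationError

__all__ = ["filter_by_quality", "residualize"]

log = logging.getLogger(__name__)


def filter_by_quality(expr: ExpressionMatrix, min_quality: float) -> ExpressionMatrix:
    """Keep samples with quality strictly above ``min_quality``, order preserved."""
    if expr.quality is None:
        raise ValidationError("expression matrix has no quality scores")
    keep = expr.sample_ids[expr.quality.to_numpy(float) > min_quality]
    if len(keep) == 0:
        raise ValidationError(f"no samples with quality > {min_quality}")
    return expr.subset_samples(keep)


def residualize(expr: ExpressionMatrix, covars: CovariateTable) -> ExpressionMatrix:
    """OLS residuals of each gene on intercept + covariates.

    Genes containing missing values are dropped (with a logged count)
    rather than imputed. Residuals are computed for all genes at once via a
    single least-squares solve; each residualized gene has zero mean and is
    orthogonal to every covariate column.
    """
    covars = covars.aligned_to(expr.sample_ids)
    X = covars.design_matrix()

    values = expr.values
    has_na = values.isna().any(axis=1)
    if has_na.any():
        log.info("dropping %d genes with missing values", int(has_na.sum()))
        values = values.loc[~has_na]
    if values.empty:
        raise ValidationError("no genes left after dropping missing values")

    Y = values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(resid.T, index=values.index, columns=values.columns)
    return ExpressionMatrix(out, expr.quality)
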