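"""Normalization, log transform, and covariate adjustment.

These transforms are shared by every expression stage: median-of-ratios
size factors, ``log2(count/sf + pseudocount)``, and per-gene OLS removal of
nuisance covariates (sex, batch, library type) with the gene grand mean
restored so fold changes stay interpretable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lhasig._design import build_design, check_full_rank, ols_fit
from lhasig.containers import CountMatrix, ExpressionMatrix

#: Columns that encode the biological contrasts; never removed as nuisance.
PROTECTED_COLUMNS = ("group", "age")


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, computed on
    genes positive in every sample; if no such gene exists, genes positive in
    >= 90% of samples are used with per-sample available ratios.
    """
    values = counts.counts if isinstance(counts, CountMatrix) else counts
    X = values.values.astype(float)
    if X.size == 0:
        raise ValueError("empty count matrix")
    if (X.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero count")

    all_positive = (X > 0).all(axis=1)
    if all_positive.any():
        sub = X[all_positive]
        log_geomean = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geomean[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        frac_positive = (X > 0).mean(axis=1)
        usable = frac_positive >= 0.9
        if not usable.any():
            raise ValueError("no gene positive in >= 90% of samples")
        sub = X[usable]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        log_geomean = np.nanmean(logs, axis=1)
        ratios = logs - log_geomean[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="size_factor")


def log_normalize(
    counts: CountMatrix, factors: pd.Series | None = None, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """``log2(count / size_factor + pseudocount)`` per entry."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.loc[counts.sample_ids]
    values = np.log2(counts.counts.values / factors.values[None, :] + pseudocount)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        metadata=counts.metadata,
        provenance={
            "size_factors": {s: float(f) for s, f in factors.items()},
            "pseudocount": pseudocount,
            "adjusted_covariates": [],
        },
    )


def remove_covariate_effects(expr: ExpressionMatrix, covariates) -> ExpressionMatrix:
    """Residualize each gene on the covariate design and restore its grand
    mean.

    ``group`` and ``age`` are refused: the biological contrast must never be
    absorbed into the nuisance design.  Raises with the offending column
    names if the design is rank deficient.
    """
    covariates = list(covariates)
    for col in covariates:
        if col in PROTECTED_COLUMNS:
            raise ValueError(
                f"{col!r} encodes the biological contrast and cannot be "
                "removed as a nuisance covariate"
            )
    if expr.metadata is None:
        raise ValueError("expression matrix has no sample metadata")
    design = build_design(expr.metadata, covariates)
    check_full_rank(design)

    Y = expr.values.values.T  # samples x genes
    _, resid, _, _ = ols_fit(design.values, Y)
    grand_mean = expr.values.values.mean(axis=1)
    adjusted = resid.T + grand_mean[:, None]

    provenance = dict(expr.provenance)
    provenance["adjusted_covariates"] = (
        list(provenance.get("adjusted_covariates", [])) + covariates
    )
    return ExpressionMatrix(
        values=pd.DataFrame(
            adjusted, index=expr.values.index, columns=expr.values.columns
        ),
        metadata=expr.metadata,
        provenance=provenance,
    )
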