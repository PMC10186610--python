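"""Per-cohort two-group differential expression and DEG calling.

The statistic is ordinary least squares on log2-normalized expression with
the group indicator plus nuisance covariates in the design; the group
coefficient is the log2 fold change (case minus control) and its t statistic
yields a two-sided p-value with the residual degrees of freedom.  This is a
deliberate, fully specified replacement for negative-binomial Wald testing:
its type-I calibration is verified on null simulations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lhasig._design import build_design, check_full_rank, ols_fit
from lhasig.containers import ExpressionMatrix, GeneSet


def de_two_group(
    expr: ExpressionMatrix,
    group_column: str = "group",
    covariates=(),
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Differential expression table with columns
    ``base_mean, log2FC, t, p, padj``.

    Genes with zero residual variance (e.g. constant genes) get t = 0 and
    p = 1 rather than being dropped, so gene universes stay aligned across
    cohorts.
    """
    if expr.metadata is None:
        raise ValueError("expression matrix has no sample metadata")
    groups = expr.metadata[group_column].astype(str)
    levels = set(groups)
    if not {case, control} <= levels:
        raise ValueError(f"groups {case!r}/{control!r} not found in {sorted(levels)}")
    if (groups == case).sum() < 2 or (groups == control).sum() < 2:
        raise ValueError("need >= 2 samples per group")

    design = build_design(expr.metadata, covariates)
    design["__group__"] = (groups == case).astype(float).values
    check_full_rank(design)

    X = design.values
    Y = expr.values.values.T  # samples x genes
    beta, _, sigma2, xtx_inv = ols_fit(X, Y)
    g = design.columns.get_loc("__group__")
    log2fc = beta[g]
    se = np.sqrt(sigma2 * xtx_inv[g, g])
    dof = X.shape[0] - X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), 1.0)

    pseudocount = expr.provenance.get("pseudocount", 1.0)
    base_mean = np.maximum(2.0 ** expr.values.values - pseudocount, 0.0).mean(axis=1)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"base_mean": base_mean, "log2FC": log2fc, "t": t, "p": p, "padj": padj},
        index=expr.values.index,
    )


def call_degs(
    de: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float | None = 1.2,
    use_adjusted: bool = False,
    name_prefix: str = "DEG",
) -> tuple[GeneSet, GeneSet]:
    """Threshold a DE table into directional gene sets.

    Inequalities are strict on both axes: a gene is called when
    ``p < p_threshold`` and ``2**|log2FC| > fc_threshold``.  With
    ``fc_threshold=None`` only the p filter applies and direction comes from
    the fold-change sign — the convention used for microarray validation
    cohorts (p < 0.01, no fold-change filter).
    """
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")
    pvals = de["padj"] if use_adjusted else de["p"]
    p_pass = pvals < p_threshold
    if fc_threshold is None:
        up = p_pass & (de["log2FC"] > 0)
        down = p_pass & (de["log2FC"] < 0)
    else:
        if fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        log2_cut = np.log2(fc_threshold)
        up = p_pass & (de["log2FC"] > log2_cut)
        down = p_pass & (de["log2FC"] < -log2_cut)
    return (
        GeneSet.from_iterable(f"{name_prefix}_up", de.index[up], "up"),
        GeneSet.from_iterable(f"{name_prefix}_down", de.index[down], "down"),
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
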