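"""Bulk immune cell-type deconvolution against a signature matrix.

Per-sample non-negative least squares against the signature columns,
followed by sum-to-one normalization; cell types estimated at exactly zero
in more than half the samples are dropped and the remainder renormalized.
NNLS is a deterministic, dependency-light replacement for support-vector
regression deconvolution; the substitution is recorded in the estimate's
metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

ZERO_TOL = 1e-10


@dataclass
class ProportionEstimate:
    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    residual_norm: pd.Series
    degenerate: list = field(default_factory=list)  # samples that solved to 0
    meta: dict = field(default_factory=dict)


def nnls_proportions(bulk: pd.DataFrame, signature: pd.DataFrame) -> ProportionEstimate:
    """Estimate cell-type proportions for each bulk sample.

    ``bulk`` is genes x samples, ``signature`` genes x cell types; the gene
    universes are intersected (>= 10 shared genes required).  A sample whose
    NNLS solution is all-zero is reported as uniform and flagged.
    """
    shared = signature.index.intersection(bulk.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared with the signature (< 10)")
    S = signature.loc[shared].values
    if (S.sum(axis=0) == 0).any():
        raise ValueError("signature has an all-zero cell-type column")
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn("signature matrix is rank deficient", stacklevel=2)
    B = bulk.loc[shared].values

    k = S.shape[1]
    props = np.empty((B.shape[1], k))
    resid = np.empty(B.shape[1])
    degenerate = []
    for j in range(B.shape[1]):
        x, r = nnls(S, B[:, j])
        x[x < ZERO_TOL] = 0.0
        total = x.sum()
        if total == 0.0:
            props[j] = 1.0 / k
            degenerate.append(bulk.columns[j])
            warnings.warn(
                f"sample {bulk.columns[j]!r} solved to the zero vector; "
                "reporting uniform proportions",
                stacklevel=2,
            )
        else:
            props[j] = x / total
        resid[j] = r
    return ProportionEstimate(
        proportions=pd.DataFrame(props, index=bulk.columns, columns=signature.columns),
        residual_norm=pd.Series(resid, index=bulk.columns, name="residual_norm"),
        degenerate=degenerate,
        meta={
            "method": "nnls",
            "n_shared_genes": int(len(shared)),
            "signature_coverage": float(len(shared) / signature.shape[0]),
        },
    )


def filter_celltypes(
    estimate: ProportionEstimate, zero_fraction: float = 0.5
) -> ProportionEstimate:
    """Drop cell types whose estimated proportion is zero in more than
    ``zero_fraction`` of samples; renormalize the remaining columns per
    sample (ratios among retained types are preserved)."""
    props = estimate.proportions
    zero_share = (props.values <= ZERO_TOL).mean(axis=0)
    keep = props.columns[zero_share <= zero_fraction]
    if len(keep) == 0:
        raise ValueError("zero-proportion filter removed every cell type")
    kept = props[keep]
    kept = kept.div(kept.sum(axis=1).replace(0.0, np.nan), axis=0).fillna(
        1.0 / len(keep)
    )
    meta = dict(estimate.meta)
    meta["dropped_celltypes"] = [c for c in props.columns if c not in set(keep)]
    return ProportionEstimate(
        proportions=kept,
        residual_norm=estimate.residual_norm,
        degenerate=list(estimate.degenerate),
        meta=meta,
    )


def compare_proportions(
    estimate: ProportionEstimate, groups: pd.Series
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum comparison per cell type, BH adjusted."""
    props = estimate.proportions
    groups = groups.loc[props.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a, b = (props[groups == lvl] for lvl in levels)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for ct in props.columns:
        stat, p = stats.mannwhitneyu(a[ct], b[ct], alternative="two-sided")
        rows.append((ct, a[ct].mean(), b[ct].mean(), stat, p))
    table = pd.DataFrame(
        rows, columns=["cell_type", f"mean_{levels[0]}", f"mean_{levels[1]}", "U", "p"]
    )
    table["padj"] = multipletests(table["p"].values, method="fdr_bh")[1]
    return table
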