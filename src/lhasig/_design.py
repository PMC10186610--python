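"""Design-matrix construction shared by the OLS-based stages."""

from __future__ import annotations

import numpy as np
import pandas as pd


def build_design(
    metadata: pd.DataFrame, columns, add_intercept: bool = True
) -> pd.DataFrame:
    """Numeric design matrix from metadata columns.

    Numeric columns enter as-is; categorical/object columns are dummy-coded
    with the first level (sorted) as reference.  Constant columns are dropped
    (they are absorbed by the intercept).
    """
    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"intercept": 1.0}, index=metadata.index))
    for col in columns:
        if col not in metadata.columns:
            raise KeyError(f"metadata has no column {col!r}")
        values = metadata[col]
        if pd.api.types.is_numeric_dtype(values):
            if values.nunique() > 1:
                parts.append(values.astype(float).to_frame(col))
        else:
            levels = sorted(values.astype(str).unique())
            for level in levels[1:]:
                parts.append(
                    (values.astype(str) == level).astype(float).to_frame(f"{col}[{level}]")
                )
    design = pd.concat(parts, axis=1)
    return design


def check_full_rank(design: pd.DataFrame) -> None:
    """Raise naming the offending columns if the design is rank deficient."""
    X = design.values
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns via pivoted QR on the transpose trick
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [design.columns[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or list(design.columns)}"
        )


def ols_fit(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of many response columns on one design.

    Parameters
    ----------
    X : (n, p) design; Y : (n, G) responses (one column per gene).

    Returns
    -------
    beta : (p, G); resid : (n, G); sigma2 : (G,) residual variances with
    ``n - p`` degrees of freedom; xtx_inv : (p, p).
    """
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    if dof <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    sigma2 = (resid**2).sum(axis=0) / dof
    return beta, resid, sigma2, xtx_inv
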