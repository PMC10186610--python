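"""Co-expression module detection and module-trait correlation.

The network is the unsigned soft-threshold adjacency ``|cor|^beta`` over
genes, turned into a topological overlap matrix (TOM); modules are found by
average-linkage clustering on TOM dissimilarity with a static tree cut,
a minimum module size, and iterative merging of modules whose eigengenes
are nearly collinear.  A module eigengene is the first principal component
of the standardized module submatrix, sign-fixed to correlate non-negatively
with the module's mean expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class Eigengene:
    module_id: int
    scores: pd.Series  # per-sample, unit norm
    variance_explained: float


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module id, 0 = unassigned
    soft_power: float
    sizes: dict


def adjacency(expr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^power (genes x genes,
    zero diagonal)."""
    cor = np.corrcoef(expr.values)
    np.fill_diagonal(cor, 0.0)
    adj = np.abs(cor) ** power
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of log10 p(k) vs log10 k over equal-occupancy bins.

    Returns (signed R^2, slope); the R^2 is negated when the slope is
    positive, matching the convention that scale-free topology requires a
    decreasing degree distribution.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    quantiles = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if len(quantiles) < 4:
        return 0.0, 0.0
    quantiles[-1] += 1e-12
    density, means = [], []
    for lo, hi in zip(quantiles[:-1], quantiles[1:]):
        mask = (k >= lo) & (k < hi)
        if mask.sum() > 0 and hi > lo:
            density.append(mask.mean() / (hi - lo))  # equal-occupancy bins
            means.append(k[mask].mean())
    if len(density) < 3:
        return 0.0, 0.0
    x = np.log10(np.array(means))
    y = np.log10(np.array(density))
    slope, _, r, _, _ = stats.linregress(x, y)
    if not (np.isfinite(slope) and np.isfinite(r)):
        return 0.0, 0.0
    r2 = r**2
    return (-r2 if slope > 0 else r2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame, candidate_powers=tuple(range(1, 13)), r2_cut: float = 0.8
) -> tuple[float, pd.DataFrame]:
    """Choose the smallest power reaching the scale-free fit cut.

    Returns (power, fit table with columns power, r2, slope,
    mean_connectivity).  If no candidate reaches ``r2_cut`` the max-R^2
    power is returned.
    """
    rows = []
    for beta in candidate_powers:
        adj = adjacency(expr, beta).values
        k = adj.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append((beta, r2, slope, float(k.mean())))
    fit = pd.DataFrame(rows, columns=["power", "r2", "slope", "mean_connectivity"])
    passing = fit[fit["r2"] >= r2_cut]
    power = float(passing["power"].iloc[0]) if len(passing) else float(
        fit.loc[fit["r2"].idxmax(), "power"]
    )
    return power, fit


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency with zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    unit diagonal.
    """
    if isinstance(adj, pd.DataFrame):
        index = adj.index
        A = adj.values.astype(float)
    else:
        A = np.asarray(adj, dtype=float)
        index = pd.RangeIndex(A.shape[0])
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=index, columns=index)


def module_eigengene(expr: pd.DataFrame, module_genes, module_id: int = 0) -> Eigengene:
    """First principal component of the standardized module submatrix.

    ``expr`` is genes x samples.  Scores are the unit-norm right singular
    vector over samples; the sign is fixed so the eigengene correlates
    non-negatively with the module's mean standardized profile.
    """
    sub = expr.loc[list(module_genes)].values
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (sub - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    total = (s**2).sum()
    var_explained = float(s[0] ** 2 / total) if total > 0 else 0.0
    reference = z.mean(axis=0)
    if np.dot(scores, reference) < 0:
        scores = -scores
    return Eigengene(
        module_id=module_id,
        scores=pd.Series(scores, index=expr.columns, name=f"ME{module_id}"),
        variance_explained=var_explained,
    )


def detect_modules(
    tom_dissimilarity: pd.DataFrame,
    expr: pd.DataFrame,
    min_size: int = 30,
    merge_height: float = 0.1,
    cut_height: float = 0.99,
    soft_power: float = np.nan,
) -> ModuleAssignment:
    """Average-linkage clustering on TOM dissimilarity with a static cut.

    Candidate clusters smaller than ``min_size`` fall into module 0
    (unassigned); modules whose eigengenes correlate above
    ``1 - merge_height`` are merged iteratively.  Final module ids are
    1..M in decreasing size order.
    """
    D = tom_dissimilarity.values
    genes = tom_dissimilarity.index
    condensed = squareform((D + D.T) / 2.0, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    labels[labels.isin(sizes[sizes < min_size].index)] = 0

    # iterative merge of near-collinear modules
    while True:
        ids = sorted(set(labels) - {0})
        if len(ids) < 2:
            break
        eigs = {
            mid: module_eigengene(expr, labels.index[labels == mid], mid).scores
            for mid in ids
        }
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                r = abs(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if r > 1.0 - merge_height and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a

    ids = sorted(set(labels) - {0}, key=lambda m: (-(labels == m).sum(), m))
    relabel = {old: new + 1 for new, old in enumerate(ids)}
    relabel[0] = 0
    labels = labels.map(relabel).rename("module")
    return ModuleAssignment(
        labels=labels,
        soft_power=soft_power,
        sizes={int(m): int((labels == m).sum()) for m in sorted(set(labels))},
    )


def correlate_with_trait(eigengenes: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a sample trait.

    ``eigengenes`` is samples x modules.  Returns r, p (two-sided, t-based)
    and BH-adjusted p per module.
    """
    trait = trait.loc[eigengenes.index].astype(float)
    if trait.std() == 0:
        raise ValueError("trait is constant; correlation undefined")
    rows = []
    for col in eigengenes.columns:
        r, p = stats.pearsonr(eigengenes[col].values, trait.values)
        rows.append((col, float(r), float(p)))
    table = pd.DataFrame(rows, columns=["module", "r", "p"])
    table["padj"] = multipletests(table["p"].values, method="fdr_bh")[1]
    return table


def flag_sample_outliers(expr: pd.DataFrame, z_cut: float = 3.0) -> list:
    """Flag samples whose standardized connectivity (sum of inter-sample
    correlations) falls below ``-z_cut``."""
    cor = np.corrcoef(expr.values.T)
    np.fill_diagonal(cor, 0.0)
    connectivity = cor.sum(axis=1)
    sd = connectivity.std()
    if sd == 0:
        return []
    z = (connectivity - connectivity.mean()) / sd
    return sorted(expr.columns[z < -z_cut])
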