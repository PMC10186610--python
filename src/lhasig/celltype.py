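"""Cell-type enrichment, gene scoring/clustering, signature scores, ORA.

GSEA here is the weighted Kolmogorov-Smirnov running-sum statistic on a
pre-ranked list with a gene-label permutation null: hits increment the
running sum by |score|^p normalized over in-set scores, misses decrement by
1/(N - m); the enrichment score is the signed maximal deviation.  NES
normalizes by the mean magnitude of same-sign null scores and the p-value is
the same-sign empirical tail with the add-one rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from lhasig.containers import GeneSet
from lhasig.consensus import hypergeometric_overlap_p


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float | None
    p: float | None
    n_perm: int
    leading_edge: list


def rank_genes_for_celltype(
    expr: pd.DataFrame, labels: pd.Series, target_type: str
) -> pd.Series:
    """Rank genes by mean expression in the target cell type minus the mean
    in all other cells (cells x genes input; descending scores, ties broken
    by gene id)."""
    labels = labels.loc[expr.index]
    mask = (labels == target_type).values
    if not mask.any():
        raise ValueError(f"no cells labelled {target_type!r}")
    target_mean = expr.values[mask].mean(axis=0)
    if (~mask).any():
        score = target_mean - expr.values[~mask].mean(axis=0)
    else:
        score = target_mean
    ranked = pd.Series(score, index=expr.columns, name="score")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    return ranked.loc[order]


def _running_es(
    scores: np.ndarray, hit: np.ndarray, weight_p: float
) -> tuple[float, int]:
    """Signed maximal deviation of the weighted KS running sum and its
    position (scores assumed sorted descending; hit is a boolean mask)."""
    n = len(scores)
    m = int(hit.sum())
    weights = np.abs(scores) ** weight_p
    hit_sum = weights[hit].sum()
    if hit_sum == 0:  # all in-set weights zero (e.g. p>0 with zero scores)
        inc = np.where(hit, 1.0 / m, 0.0)
    else:
        inc = np.where(hit, weights / hit_sum, 0.0)
    dec = np.where(hit, 0.0, 1.0 / (n - m))
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked GSEA of one gene set with a gene-label permutation null.

    ``ranked`` maps gene ids to scores sorted descending.  Requires the set
    to hit at least one but not all ranked genes.
    """
    scores = ranked.values.astype(float)
    genes = ranked.index
    hit = np.asarray(pd.Index(genes).isin(list(gene_set.members)))
    m = int(hit.sum())
    n = len(genes)
    if m == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if m == n:
        raise ValueError("gene set covers the entire ranked list")

    es, peak = _running_es(scores, hit, weight_p)
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hit[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak + 1 :], hit[peak + 1 :]) if h]

    # vectorized permutation null: each row is a random m-subset
    rng = np.random.default_rng(seed)
    u = rng.random((n_perm, n))
    kth = np.partition(u, m - 1, axis=1)[:, m - 1 : m]
    hits = u <= kth
    weights = np.abs(scores) ** weight_p
    hit_w = hits * weights[None, :]
    hit_sums = hit_w.sum(axis=1, keepdims=True)
    safe = np.where(hit_sums > 0, hit_sums, 1.0)
    inc = np.where(hits, hit_w / safe, -1.0 / (n - m))
    running = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    null_es = running[np.arange(n_perm), idx]

    same_sign = null_es > 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same < 3:
        warnings.warn(
            f"only {n_same} same-sign null enrichment scores; NES/p undefined",
            stacklevel=2,
        )
        nes = p = None
    else:
        nes = es / float(np.abs(null_es[same_sign]).mean())
        extreme = np.abs(null_es[same_sign]) >= abs(es)
        p = (1 + int(extreme.sum())) / (n_same + 1)
    return EnrichmentResult(
        set_name=gene_set.name, es=es, nes=nes, p=p, n_perm=n_perm,
        leading_edge=leading,
    )


def gene_cell_scores(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-gene z-score across all cells, averaged within each cell type
    (genes x cell types)."""
    labels = labels.loc[expr.index]
    X = expr.values
    mean = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    types = sorted(labels.unique())
    out = np.column_stack([z[(labels == t).values].mean(axis=0) for t in types])
    return pd.DataFrame(out, index=expr.columns, columns=types)


def cluster_gene_scores(scores: pd.DataFrame, k: int = 4, seed: int = 0) -> pd.Series:
    """K-means clustering of gene score profiles across cell types.

    Cluster ids are relabelled 1..k in the column order of each centroid's
    maximal cell type, so the numbering is stable across runs.
    """
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(scores.values)
    order = np.lexsort(
        (km.cluster_centers_.max(axis=1) * -1, km.cluster_centers_.argmax(axis=1))
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([relabel[r] for r in raw], index=scores.index, name="cluster")


def signature_score(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Mean per-gene z-score over the set members, per sample.

    ``expr`` is genes x samples; genes absent from the matrix are ignored;
    constant genes contribute 0.
    """
    members = [g for g in expr.index if g in gene_set.members]
    if not members:
        raise ValueError("no gene-set member present in the expression matrix")
    X = expr.loc[members].values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=0), index=expr.columns, name=gene_set.name)


def ora_hypergeometric(query: GeneSet, pathways, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in each pathway.

    ``pathways`` is a mapping name -> iterable of genes (or GeneSets).
    All sets are intersected with the universe first.
    """
    universe = frozenset(universe)
    q = query.members & universe
    if not q:
        raise ValueError("query set has no genes in the universe")
    rows = []
    items = (
        [(gs.name, gs.members) for gs in pathways]
        if not isinstance(pathways, dict)
        else list(pathways.items())
    )
    for name, members in items:
        pw = frozenset(members) & universe
        overlap = len(q & pw)
        p = hypergeometric_overlap_p(len(universe), len(q), len(pw), overlap)
        rows.append((name, overlap, len(pw), p))
    table = pd.DataFrame(rows, columns=["pathway", "overlap", "pathway_size", "p"])
    table["padj"] = multipletests(table["p"].values, method="fdr_bh")[1]
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def anova_across_groups(scores: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of per-sample scores across groups."""
    groups = groups.loc[scores.index]
    arrays = [scores[groups == g].values for g in sorted(groups.unique())]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    F, p = stats.f_oneway(*arrays)
    return float(F), float(p)
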