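"""Insulin-response correlation, promoter-binding overlap, TF analyses.

Intervals follow the BED convention throughout: 0-based, half-open,
``(chrom, start, end, name, strand)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lhasig.containers import GeneSet
from lhasig.consensus import hypergeometric_overlap_p


def stimulus_correlation(
    series: pd.DataFrame,
    reference_gene: str,
    query_genes=None,
    r_cut: float = 0.3,
) -> pd.DataFrame:
    """Pearson correlation of each query gene with a reference gene across
    stimulus conditions, classified positive/negative at |r| >= r_cut.

    Constant profiles (undefined correlation) are classified ``none`` with
    a degenerate flag.
    """
    if reference_gene not in series.index:
        raise ValueError(f"reference gene {reference_gene!r} not in series")
    if series.shape[1] < 3:
        raise ValueError("need >= 3 conditions for correlation")
    ref = series.loc[reference_gene].values.astype(float)
    if ref.std() == 0:
        raise ValueError("reference profile is constant")
    if query_genes is None:
        query_genes = [g for g in series.index if g != reference_gene]
    rows = []
    for gene in query_genes:
        prof = series.loc[gene].values.astype(float)
        if prof.std() == 0:
            rows.append((gene, np.nan, "none", True))
            continue
        r, _ = stats.pearsonr(prof, ref)
        if abs(r) >= r_cut:
            cls = "positive" if r > 0 else "negative"
        else:
            cls = "none"
        rows.append((gene, float(r), cls, False))
    return pd.DataFrame(rows, columns=["gene", "r", "class", "degenerate"]).set_index(
        "gene"
    )


def promoters_from_genes(
    genes: pd.DataFrame, upstream: int = 2000, downstream: int = 500
) -> pd.DataFrame:
    """Promoter windows around each gene's TSS, strand-aware, clipped at 0.

    On the + strand the TSS is ``start`` and the promoter is
    ``[TSS - upstream, TSS + downstream)``; on the - strand the TSS is
    ``end`` and the window mirrors.
    """
    out = genes.copy()
    plus = genes["strand"] != "-"
    tss = np.where(plus, genes["start"], genes["end"])
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    out["start"] = np.maximum(start, 0)
    out["end"] = np.maximum(end, 1)
    return out


def interval_overlap(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All overlapping record pairs between two interval sets.

    Half-open overlap test (a.start < b.end and b.start < a.end) via a
    per-chromosome sorted sweep; returns a DataFrame with the positional
    indices and names of overlapping records from each side.
    """
    pairs = []
    a_idx = np.arange(len(a))
    b_idx = np.arange(len(b))
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        am = a["chrom"].values == chrom
        bm = b["chrom"].values == chrom
        a_start = a["start"].values[am]
        a_end = a["end"].values[am]
        ai = a_idx[am]
        order_a = np.argsort(a_start, kind="stable")
        a_start, a_end, ai = a_start[order_a], a_end[order_a], ai[order_a]
        b_start = b["start"].values[bm]
        b_end = b["end"].values[bm]
        bi = b_idx[bm]
        order_b = np.argsort(b_start, kind="stable")
        b_start, b_end, bi = b_start[order_b], b_end[order_b], bi[order_b]

        j0 = 0
        active: list = []
        for k in range(len(a_start)):
            while j0 < len(b_start) and b_start[j0] < a_end[k]:
                active.append(j0)
                j0 += 1
            active = [j for j in active if b_end[j] > a_start[k]]
            for j in active:
                if b_start[j] < a_end[k] and a_start[k] < b_end[j]:
                    pairs.append((ai[k], bi[j]))
    pairs.sort()
    names_a = a["name"].values if "name" in a.columns else a_idx.astype(str)
    names_b = b["name"].values if "name" in b.columns else b_idx.astype(str)
    return pd.DataFrame(
        {
            "a_index": [p[0] for p in pairs],
            "b_index": [p[1] for p in pairs],
            "a_name": [names_a[p[0]] for p in pairs],
            "b_name": [names_b[p[1]] for p in pairs],
        }
    )


def binding_ratio_per_cluster(
    lha_clusters, bound_genes: GeneSet, universe
) -> pd.DataFrame:
    """Fraction of each cluster's genes carrying a binding site, with an
    enrichment p against the universe-wide bound fraction."""
    universe = frozenset(universe)
    bound = frozenset(bound_genes.members) & universe
    items = (
        list(lha_clusters.items())
        if isinstance(lha_clusters, dict)
        else [(gs.name, gs) for gs in lha_clusters]
    )
    rows = []
    for label, cluster in items:
        members = frozenset(
            cluster.members if isinstance(cluster, GeneSet) else cluster
        ) & universe
        if not members:
            rows.append((label, 0, 0, np.nan, 1.0))
            continue
        overlap = len(members & bound)
        ratio = overlap / len(members)
        p = hypergeometric_overlap_p(len(universe), len(members), len(bound), overlap)
        rows.append((label, len(members), overlap, ratio, p))
    return pd.DataFrame(
        rows, columns=["cluster", "cluster_size", "n_bound", "ratio", "p"]
    )


def tf_specificity_filter(
    tf_scores: pd.DataFrame, phagocyte_types, fold_cut: float = 2.0
) -> list:
    """Retain TFs whose expression is specific to professional phagocytes.

    ``tf_scores`` is TFs x cell types (e.g. mean per-type z-scores).  Scores
    are shifted to a positive scale (global minimum to a small epsilon); a
    TF is retained when its minimum over phagocyte types strictly exceeds
    ``fold_cut`` times its maximum over the remaining types.
    """
    phagocyte_types = [t for t in phagocyte_types if t in tf_scores.columns]
    other = [t for t in tf_scores.columns if t not in set(phagocyte_types)]
    if not phagocyte_types or not other:
        raise ValueError("need both phagocyte and non-phagocyte cell types")
    shifted = tf_scores - tf_scores.values.min() + 0.1
    keep = shifted[phagocyte_types].min(axis=1) > fold_cut * shifted[other].max(axis=1)
    return sorted(tf_scores.index[keep])


def tf_target_enrichment(tf_table, query: GeneSet, universe) -> pd.DataFrame:
    """Hypergeometric enrichment of the query set in each TF's targets."""
    universe = frozenset(universe)
    q = frozenset(query.members) & universe
    if not q:
        raise ValueError("query set is empty in the universe")
    rows = []
    for tf, targets in tf_table.items():
        t = frozenset(targets) & universe
        if not t:
            raise ValueError(f"TF {tf!r} has an empty target set")
        overlap = len(q & t)
        p = hypergeometric_overlap_p(len(universe), len(q), len(t), overlap)
        rows.append((tf, len(t), overlap, p))
    table = pd.DataFrame(rows, columns=["tf", "n_targets", "overlap", "p"])
    table["padj"] = multipletests(table["p"].values, method="fdr_bh")[1]
    return table.sort_values("p", kind="stable").reset_index(drop=True)
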