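"""Two-group methylome delta-beta analysis.

Per-probe delta beta (group B minus group A mean), global skewness of the
delta-beta distribution (negative skew = net hypomethylation in B),
differentially methylated probe (DMP) calling by Welch t-test with
|delta beta| and adjusted-p cuts, probe-to-gene mapping, and cross
tabulation of methylation direction against labelled LHA gene clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lhasig.containers import GeneSet
from lhasig.consensus import hypergeometric_overlap_p

LN2 = np.log(2.0)


def _check_probes(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if not a.index.equals(b.index):
        raise ValueError("beta matrices must share an identical probe set")


def delta_beta(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Per-probe mean(beta_B) - mean(beta_A)."""
    _check_probes(a, b)
    return (b.mean(axis=1) - a.mean(axis=1)).rename("delta_beta")


def skewness(values) -> float:
    """Fisher-Pearson standardized third moment g1 = m3 / m2^(3/2)."""
    return float(stats.skew(np.asarray(values, dtype=float), bias=True))


def call_dmps(
    a: pd.DataFrame,
    b: pd.DataFrame,
    d_cut: float = 0.1,
    p_cut: float = 0.01,
    use_m_values: bool = False,
) -> pd.DataFrame:
    """DMP table with columns ``delta_beta, p, padj, call``.

    The test is Welch's t per probe, on beta values by default or on
    M-values (logit2 beta) when ``use_m_values`` — the M scale stabilizes
    the variance near the 0/1 boundaries.  Calls use strict inequalities:
    hyper iff padj < p_cut and delta_beta > d_cut; hypo symmetric.
    """
    _check_probes(a, b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    if use_m_values:
        clip = lambda x: np.clip(x, 1e-6, 1 - 1e-6)  # noqa: E731
        xa = np.log2(clip(a.values) / (1 - clip(a.values)))
        xb = np.log2(clip(b.values) / (1 - clip(b.values)))
    else:
        xa, xb = a.values, b.values
    _, p = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    db = b.values.mean(axis=1) - a.values.mean(axis=1)
    call = np.where(
        (padj < p_cut) & (db > d_cut),
        "hyper",
        np.where((padj < p_cut) & (db < -d_cut), "hypo", "ns"),
    )
    return pd.DataFrame(
        {"delta_beta": db, "p": p, "padj": padj, "call": call}, index=a.index
    )


def map_probes_to_genes(
    dmps: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[GeneSet, GeneSet, dict]:
    """Map called probes to gene sets per direction.

    ``annotation`` needs columns ``probe`` and ``gene``.  Returns
    (hyper genes, hypo genes, info) where info records conflicting genes
    (hit in both directions) and the number of unannotated called probes.
    """
    probe_gene = annotation.set_index("probe")["gene"]
    out = {"hyper": set(), "hypo": set()}
    unannotated = 0
    for direction in ("hyper", "hypo"):
        probes = dmps.index[dmps["call"] == direction]
        for probe in probes:
            gene = probe_gene.get(probe)
            if gene is None or (isinstance(gene, float) and np.isnan(gene)):
                unannotated += 1
            else:
                out[direction].add(gene)
    conflicts = sorted(out["hyper"] & out["hypo"])
    info = {"conflict_genes": conflicts, "n_unannotated_called_probes": unannotated}
    return (
        GeneSet.from_iterable("methyl_hyper", out["hyper"], "up"),
        GeneSet.from_iterable("methyl_hypo", out["hypo"], "down"),
        info,
    )


def classify_lha_methylation(
    hyper: GeneSet, hypo: GeneSet, lha_clusters, universe
) -> pd.DataFrame:
    """Contingency of methylation direction against labelled LHA clusters.

    ``lha_clusters`` maps cluster label -> GeneSet (or iterable of genes).
    Returns one row per (cluster, direction) with overlap counts and the
    upper-tail hypergeometric p against the shared universe.
    """
    universe = frozenset(universe)
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
        for direction, gs in (("hyper", hyper), ("hypo", hypo)):
            hits = frozenset(gs.members) & universe
            overlap = len(members & hits)
            p = hypergeometric_overlap_p(
                len(universe), len(members), len(hits), overlap
            )
            rows.append((label, direction, len(members), len(hits), overlap, p))
    return pd.DataFrame(
        rows,
        columns=["cluster", "direction", "cluster_size", "direction_size",
                 "overlap", "p"],
    )
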