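"""Common-aging trajectory selection and LHA derivation.

Age-associated genes are found with a nested-model F test (decade-bin factor
on top of covariates), summarized as z-scale decade-bin mean profiles,
grouped by hierarchical clustering on Pearson dissimilarity, and screened
with a slope statistic on the last three decade bins:

    slope = (m_60-69 - m_50-59) * (m_70-79 - m_60-69)

A positive slope means the trajectory keeps moving in the same direction
beyond age 50.  Groups whose final-decade change is below ``flat_epsilon``
are rejected as flat even when the slope is positive; groups induced only in
the final decade (a jump of at least ``spike_delta`` above every earlier
bin) are additionally selected.  Tiny groups (fewer than ``min_size`` genes)
are never selected.  The aging sets so obtained are subtracted from the
consensus DEG sets to leave the longevity-and-healthy-aging (LHA) genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from lhasig._design import build_design, check_full_rank, ols_fit
from lhasig.containers import ExpressionMatrix, GeneSet
from lhasig.simulate import DECADE_BINS

BIN_EDGES = np.array([20, 30, 40, 50, 60, 70, 80])


@dataclass
class PatternGroup:
    group_id: int
    members: list
    centroid: np.ndarray  # six z-scale bin means
    slope_value: float
    selected: bool = False
    direction: str = "none"
    reason: str = ""


@dataclass
class LHAResult:
    lha_up: GeneSet
    lha_down: GeneSet
    removed_aging: GeneSet
    provenance: dict = field(default_factory=dict)  # gene -> removal sources


def assign_decade_bins(ages) -> pd.Series:
    """Map ages 20-79 onto the six decade bin labels."""
    ages = pd.Series(ages)
    idx = np.digitize(ages.values, BIN_EDGES[1:-1])
    if (ages < 20).any() or (ages >= 80).any():
        raise ValueError("ages must lie in [20, 80)")
    return pd.Series([DECADE_BINS[i] for i in idx], index=ages.index, name="age_bin")


def age_association_test(
    expr: ExpressionMatrix, ages=None, covariates=()
) -> pd.DataFrame:
    """Per-gene F test of the decade-bin factor over a covariate-only model.

    Returns a DataFrame with columns ``F, p, padj``; significance is
    conventionally taken at padj < 0.05.
    """
    if ages is None:
        ages = expr.metadata["age"]
    bins = assign_decade_bins(ages)
    counts = bins.value_counts()
    if set(counts.index) != set(DECADE_BINS) or (counts < 2).any():
        raise ValueError("each of the six decade bins needs >= 2 samples")

    meta = expr.metadata.copy() if expr.metadata is not None else pd.DataFrame(index=bins.index)
    meta["__bin__"] = bins.values
    reduced = build_design(meta, covariates)
    full = build_design(meta, list(covariates) + ["__bin__"])
    check_full_rank(full)

    Y = expr.values.values.T
    _, resid_full, _, _ = ols_fit(full.values, Y)
    _, resid_red, _, _ = ols_fit(reduced.values, Y)
    rss_full = (resid_full**2).sum(axis=0)
    rss_red = (resid_red**2).sum(axis=0)
    df_num = full.shape[1] - reduced.shape[1]
    df_den = full.shape[0] - full.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    F = np.where(rss_full > 0, F, 0.0)
    p = np.where(rss_full > 0, stats.f.sf(F, df_num, df_den), 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"F": F, "p": p, "padj": padj}, index=expr.values.index)


def bin_profiles(expr: ExpressionMatrix, ages=None) -> pd.DataFrame:
    """Z-scale decade-bin mean profiles, genes x six bins.

    Each gene is z-scored across samples (a constant gene scores 0
    everywhere), then averaged within each decade bin.
    """
    if ages is None:
        ages = expr.metadata["age"]
    bins = assign_decade_bins(ages)
    X = expr.values.values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    out = np.full((X.shape[0], 6), np.nan)
    for j, label in enumerate(DECADE_BINS):
        mask = (bins == label).values
        if mask.any():
            out[:, j] = z[:, mask].mean(axis=1)
    if np.isnan(out).any():
        raise ValueError("every decade bin needs at least one sample")
    return pd.DataFrame(out, index=expr.values.index, columns=DECADE_BINS)


def slope_value(centroid) -> float:
    """Product of the last two consecutive bin-mean differences.

    Positive iff the profile changes in a consistent direction from the
    50-59 bin through the 70-79 bin; translation-invariant.
    """
    m = np.asarray(centroid, dtype=float)
    if m.shape[-1] != 6:
        raise ValueError("centroid must have six decade-bin means")
    return float((m[4] - m[3]) * (m[5] - m[4]))


def cluster_patterns(
    profiles: pd.DataFrame, min_corr: float = 0.7, min_size: int = 3
) -> list:
    """Group bin profiles by average-linkage clustering on 1 - Pearson.

    The tree is cut at height ``1 - min_corr``.  Groups smaller than
    ``min_size`` are kept but flagged unselectable.  Gene order is fixed
    lexicographically so the grouping is deterministic.
    """
    profiles = profiles.sort_index()
    if len(profiles) == 0:
        return []
    if len(profiles) == 1:
        labels = np.array([1])
    else:
        # genes with zero profile variance cannot enter a correlation
        # distance; give them a tiny deterministic jitter-free fallback by
        # treating them as their own cluster afterwards
        sd = profiles.values.std(axis=1)
        constant = sd == 0
        work = profiles.values[~constant]
        labels = np.zeros(len(profiles), dtype=int)
        if len(work) >= 2:
            dist = pdist(work, metric="correlation")
            tree = linkage(dist, method="average")
            labels[~constant] = fcluster(tree, t=1.0 - min_corr, criterion="distance")
        elif len(work) == 1:
            labels[~constant] = 1
        if constant.any():
            labels[constant] = labels.max() + 1

    groups = []
    for gid in sorted(set(labels)):
        mask = labels == gid
        members = list(profiles.index[mask])
        centroid = profiles.values[mask].mean(axis=0)
        groups.append(
            PatternGroup(
                group_id=int(gid),
                members=members,
                centroid=centroid,
                slope_value=slope_value(centroid),
                reason="too_small" if mask.sum() < min_size else "",
            )
        )
    return groups


def select_age_groups(
    groups,
    flat_epsilon: float = 0.05,
    spike_delta: float = 0.5,
    min_size: int = 3,
) -> tuple[GeneSet, GeneSet]:
    """Apply the slope / flatness / late-spike rules and return directional
    aging gene sets.

    A group is selected when its slope value is positive, its 60s-to-70s
    change is at least ``flat_epsilon`` in magnitude, and it has at least
    ``min_size`` members; a group whose 70-79 mean exceeds every earlier bin
    by ``spike_delta`` is selected as a late-induction pattern regardless of
    slope.  Direction is the sign of (m_70-79 - m_50-59).
    """
    up, down = set(), set()
    for g in groups:
        m = g.centroid
        last_gap = m[5] - m[4]
        spike = (m[5] - m[:5].max()) >= spike_delta
        if len(g.members) < min_size:
            g.selected = False
            g.reason = "too_small"
        elif spike:
            g.selected = True
            g.reason = "late_spike"
        elif g.slope_value > 0 and abs(last_gap) >= flat_epsilon:
            g.selected = True
            g.reason = "slope"
        else:
            g.selected = False
            g.reason = "flat" if g.slope_value > 0 else "non_monotone"
        if g.selected:
            trend = m[5] - m[3]
            g.direction = "up" if trend > 0 else ("down" if trend < 0 else "none")
            (up if g.direction == "up" else down).update(g.members)
    return (
        GeneSet.from_iterable("aging_up", up, "up"),
        GeneSet.from_iterable("aging_down", down, "down"),
    )


def derive_lha(
    cdeg_up: GeneSet,
    cdeg_down: GeneSet,
    aging_sets=(),
    external_aging: GeneSet | None = None,
) -> LHAResult:
    """Subtract aging-associated genes from the consensus DEG sets.

    Every removed gene is logged with the name(s) of the aging set(s) that
    caused its removal.
    """
    removal_sources: dict = {}
    all_aging = set()
    sources = list(aging_sets)
    if external_aging is not None:
        sources.append(external_aging)
    for gs in sources:
        for gene in gs.members:
            removal_sources.setdefault(gene, []).append(gs.name)
        all_aging |= gs.members

    lha_up = cdeg_up.members - all_aging
    lha_down = cdeg_down.members - all_aging
    removed = (cdeg_up.members | cdeg_down.members) & all_aging
    return LHAResult(
        lha_up=GeneSet.from_iterable("LHA_up", lha_up, "up"),
        lha_down=GeneSet.from_iterable("LHA_down", lha_down, "down"),
        removed_aging=GeneSet.from_iterable("removed_aging", removed),
        provenance={g: sorted(removal_sources[g]) for g in sorted(removed)},
    )
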