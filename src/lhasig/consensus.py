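"""Cross-cohort consensus gene sets and the permutation overlap null.

The consensus (cDEG) set is the exact intersection of per-cohort directional
DEG sets.  Its non-randomness is assessed by repeatedly drawing sets of the
same sizes uniformly from the tested gene universe and recording the k-way
intersection size; the analytic expectation is N * prod(n_i / N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from lhasig.containers import GeneSet


@dataclass
class OverlapNullResult:
    observed: int | None
    null_mean: float
    null_sd: float
    empirical_p: float | None
    n_perm: int
    analytic_expectation: float
    null_overlaps: np.ndarray | None = None


def intersect_sets(sets, direction: str | None = None, name: str = "consensus") -> GeneSet:
    """Exact k-way intersection of gene sets (all must share a direction if
    one is given)."""
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    if direction is not None:
        for gs in sets:
            if gs.direction != direction:
                raise ValueError(
                    f"set {gs.name!r} has direction {gs.direction!r}, "
                    f"expected {direction!r}"
                )
    members = frozenset.intersection(*(gs.members for gs in sets))
    return GeneSet(name=name, members=members, direction=direction or "none")


def permutation_overlap_null(
    universe_size: int,
    set_sizes,
    n_perm: int = 10000,
    seed: int = 0,
    observed: int | None = None,
) -> OverlapNullResult:
    """Null distribution of the k-way overlap of uniformly drawn gene sets.

    Each permutation draws, for every cohort, ``n_i`` genes without
    replacement from a universe of ``universe_size`` and records the size of
    their intersection.  The empirical p for an observed overlap uses the
    add-one rule ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    set_sizes = list(set_sizes)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    for n_i in set_sizes:
        if n_i > universe_size:
            raise ValueError(f"set size {n_i} exceeds universe {universe_size}")
    rng = np.random.default_rng(seed)

    # membership indicator per set: top-n_i of iid uniforms = uniform draw
    in_all = np.ones((n_perm, universe_size), dtype=bool)
    for n_i in set_sizes:
        u = rng.random((n_perm, universe_size))
        kth = np.partition(u, n_i - 1, axis=1)[:, n_i - 1 : n_i]
        in_all &= u <= kth
    overlaps = in_all.sum(axis=1)

    analytic = universe_size * float(np.prod([n / universe_size for n in set_sizes]))
    empirical_p = None
    if observed is not None:
        empirical_p = (1 + int((overlaps >= observed).sum())) / (n_perm + 1)
    return OverlapNullResult(
        observed=observed,
        null_mean=float(overlaps.mean()),
        null_sd=float(overlaps.std(ddof=1)),
        empirical_p=empirical_p,
        n_perm=n_perm,
        analytic_expectation=analytic,
        null_overlaps=overlaps,
    )


def overlap_fraction(query: GeneSet, reference: GeneSet) -> float:
    """Percentage of query genes found in the reference set."""
    if len(query) == 0:
        raise ValueError("empty query set")
    return 100.0 * len(query.members & reference.members) / len(query)


def hypergeometric_overlap_p(
    universe_size: int, size_a: int, size_b: int, observed: int
) -> float:
    """Upper-tail P(X >= observed) for the overlap of two fixed-size sets
    drawn from a common universe."""
    if max(size_a, size_b) > universe_size:
        raise ValueError("set size exceeds universe")
    return float(stats.hypergeom.sf(observed - 1, universe_size, size_a, size_b))
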