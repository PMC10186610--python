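"""Planted-truth recovery and calibration experiments.

Each function runs one self-contained experiment on synthetic data at the
default study conditions (cohorts of 30+30, 2,000 genes, planted log2
effects of 1.0, delta-beta of 0.2, and so on), and returns the measured
quantities.  The test suite asserts on these numbers and the acceptance
script reports them; the implementations deliberately reuse the public
pipeline operations rather than shortcuts.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy import stats

from lhasig import (
    age_patterns,
    celltype,
    coexpr,
    consensus,
    deconvolution,
    diffexpr,
    methylome,
    preprocess,
    simulate,
)
from lhasig.containers import GeneSet


def subseed(seed: int, label: str) -> int:
    """Stable independent sub-seed derived from a base seed and a label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ------------------------------------------------------------ consensus


def permutation_null_check(
    seed: int, universe: int = 100, set_size: int = 10, k: int = 3,
    n_perm: int = 10000,
) -> dict:
    """Mean k-way overlap of random sets vs the analytic expectation
    N * (n/N)**k, with the Monte-Carlo standard error."""
    null = consensus.permutation_overlap_null(
        universe, [set_size] * k, n_perm=n_perm, seed=seed
    )
    se = null.null_sd / np.sqrt(n_perm)
    return {
        "null_mean": null.null_mean,
        "analytic_expectation": null.analytic_expectation,
        "standard_error": se,
        "z": (null.null_mean - null.analytic_expectation) / se,
        "n_perm": n_perm,
    }


# ------------------------------------------------------- DE calibration


def de_null_fraction(
    seed: int, n_genes: int = 2000, n_case: int = 30, n_control: int = 30
) -> float:
    """Fraction of nominal p < 0.05 in a null two-group comparison (no
    planted effects; sex/batch/library nuisance present and adjusted)."""
    cfg = simulate.SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        cohorts=[simulate.CohortSpec("null", n_case, n_control)],
    )
    matrices, _ = simulate.simulate_multicohort_counts(cfg)
    em = preprocess.log_normalize(matrices[0])
    de = diffexpr.de_two_group(em, covariates=["sex", "batch", "library"])
    return float((de["p"] < 0.05).mean())


# ------------------------------------------------- end-to-end LHA recovery


def lha_recovery(
    seed: int,
    n_genes: int = 2000,
    n_case: int = 30,
    n_control: int = 30,
    n_longevity: int = 100,
    n_aging: int = 100,
    n_per_bin: int = 20,
) -> dict:
    """Full pipeline recovery of planted longevity genes.

    Half of each planted class is up-, half downregulated.  Aging genes are
    differentially expressed in *every* cohort (so they enter the consensus
    sets) and additionally follow monotone age trajectories in the
    age-series cohort; the LHA subtraction should remove them while keeping
    the longevity genes.
    """
    h_l, h_a = n_longevity // 2, n_aging // 2
    lu = list(range(0, h_l))
    ld = list(range(h_l, n_longevity))
    au = list(range(n_longevity, n_longevity + h_a))
    ad = list(range(n_longevity + h_a, n_longevity + n_aging))

    mc = simulate.SimulationConfig(
        seed=subseed(seed, "cohorts"),
        n_genes=n_genes,
        cohorts=[
            simulate.CohortSpec(name, n_case, n_control)
            for name in ("ChM", "LG", "LS")
        ],
        planted_shared_up=lu + au,
        planted_shared_down=ld + ad,
    )
    matrices, _ = simulate.simulate_multicohort_counts(mc)
    up_sets, down_sets = [], []
    for cm in matrices:
        em = preprocess.log_normalize(cm)
        de = diffexpr.de_two_group(em, covariates=["sex", "batch", "library"])
        up, down = diffexpr.call_degs(de, p_threshold=0.05, fc_threshold=1.2)
        up_sets.append(up)
        down_sets.append(down)
    cdeg_up = consensus.intersect_sets(up_sets, "up")
    cdeg_down = consensus.intersect_sets(down_sets, "down")

    age_cfg = simulate.AgeSeriesConfig(
        seed=subseed(seed, "ages"),
        n_genes=n_genes,
        n_per_bin=n_per_bin,
        archetypes={"monotone_up": au, "monotone_down": ad},
    )
    age_cm, _ = simulate.simulate_age_series(age_cfg)
    em = preprocess.log_normalize(age_cm)
    em = preprocess.remove_covariate_effects(em, ["sex"])
    assoc = age_patterns.age_association_test(em)
    significant = assoc.index[assoc["padj"] < 0.05]
    profiles = age_patterns.bin_profiles(em).loc[significant]
    groups = age_patterns.cluster_patterns(profiles)
    aging_up, aging_down = age_patterns.select_age_groups(groups)
    result = age_patterns.derive_lha(cdeg_up, cdeg_down, [aging_up, aging_down])

    ids = lambda idx: {f"G{i:06d}" for i in idx}  # noqa: E731
    lha = result.lha_up.members | result.lha_down.members
    longevity = ids(lu) | ids(ld)
    aging = ids(au) | ids(ad)
    return {
        "sensitivity": len(lha & longevity) / len(longevity),
        "aging_contamination": len(lha & aging) / max(len(lha), 1),
        "n_lha": len(lha),
        "n_cdeg_up": len(cdeg_up),
        "n_cdeg_down": len(cdeg_down),
    }


# ------------------------------------------------------------ deconvolution


def deconvolution_recovery(
    seed: int, n_samples: int = 20, noise_sd: float = 0.1
) -> dict:
    """Noise-free and noisy mixture recovery against the true proportions."""
    signature = simulate.simulate_signature(seed=subseed(seed, "signature"))
    props = simulate.random_proportions(
        n_samples, signature.columns, seed=subseed(seed, "props")
    )
    clean, truth = simulate.simulate_mixtures(signature, props, noise_sd=0.0)
    est_clean = deconvolution.nnls_proportions(clean, signature)
    noisy, _ = simulate.simulate_mixtures(
        signature, props, noise_sd=noise_sd, seed=subseed(seed, "noise")
    )
    est_noisy = deconvolution.nnls_proportions(noisy, signature)
    return {
        "noise_free_max_error": float(
            np.abs(est_clean.proportions.values - truth.values).max()
        ),
        "noisy_mae": float(
            np.abs(est_noisy.proportions.values - truth.values).mean()
        ),
        "n_samples": n_samples,
    }


# --------------------------------------------------------------- methylome


def methylome_skew_rate(seed: int, n_seeds: int = 100) -> float:
    """Fraction of seeds for which planted global hypomethylation yields a
    negative delta-beta skewness."""
    negative = 0
    for i in range(n_seeds):
        cfg = simulate.MethylomeConfig(
            seed=subseed(seed, f"skew{i}"),
            n_probes=2000,
            global_hypo_fraction=0.25,
        )
        a, b, _, _ = simulate.simulate_methylome(cfg)
        g1 = methylome.skewness(methylome.delta_beta(a, b).values)
        negative += g1 < 0
    return negative / n_seeds


def dmp_recovery(seed: int, n_probes: int = 2000, n_planted: int = 100) -> dict:
    """Sensitivity and FDR of DMP calling on planted |delta beta| = 0.2
    probes at n = 20 per group."""
    half = n_planted // 2
    cfg = simulate.MethylomeConfig(
        seed=seed,
        n_probes=n_probes,
        planted_hypo=range(half),
        planted_hyper=range(half, n_planted),
        delta_beta_target=0.2,
    )
    a, b, _, truth = simulate.simulate_methylome(cfg)
    dmps = methylome.call_dmps(a, b, d_cut=0.1, p_cut=0.01)
    called = dmps.index[dmps["call"] != "ns"]
    planted = truth.index[truth["role"].isin(["hypo", "hyper"])]
    n_called = len(called)
    tp = len(set(called) & set(planted))
    correct_dir = (
        (dmps.loc[planted, "call"] == truth.loc[planted, "role"]).mean()
    )
    return {
        "sensitivity": tp / len(planted),
        "fdr": (n_called - tp) / max(n_called, 1),
        "direction_accuracy": float(correct_dir),
    }


# ------------------------------------------------------------ co-expression


def coexpr_block_recovery(seed: int) -> dict:
    """Adjusted Rand index of detected modules vs three planted 50-gene
    blocks (plus unassigned noise genes)."""
    from sklearn.metrics import adjusted_rand_score

    cfg = simulate.CoexpressionConfig(seed=seed)
    expr, ages, truth = simulate.simulate_coexpression(cfg)
    power, _ = coexpr.pick_soft_threshold(expr, range(1, 9))
    tom = coexpr.tom_similarity(coexpr.adjacency(expr, power))
    modules = coexpr.detect_modules(1.0 - tom, expr, min_size=30)
    ari = adjusted_rand_score(truth.values, modules.labels.loc[truth.index].values)
    eigs = {
        f"ME{m}": coexpr.module_eigengene(
            expr, modules.labels.index[modules.labels == m], m
        ).scores
        for m in sorted(set(modules.labels) - {0})
    }
    trait = coexpr.correlate_with_trait(pd.DataFrame(eigs), ages)
    best = trait.loc[trait["r"].abs().idxmax()]
    return {
        "ari": float(ari),
        "n_modules": len(eigs),
        "age_r": float(best["r"]),
        "age_p": float(best["p"]),
    }


def age_module_sign_rate(seed: int, n_seeds: int = 100) -> float:
    """Fraction of seeds in which the planted age-loaded module's eigengene
    correlates positively with age (50-gene module, 60 samples)."""
    hits = 0
    for i in range(n_seeds):
        cfg = simulate.CoexpressionConfig(
            seed=subseed(seed, f"sign{i}"),
            n_blocks=1,
            block_size=50,
            n_noise_genes=0,
            n_samples=60,
            age_loaded_block=1,
            age_loading=0.8,
        )
        expr, ages, _ = simulate.simulate_coexpression(cfg)
        eig = coexpr.module_eigengene(expr, expr.index, 1)
        r, _ = stats.pearsonr(eig.scores.values, ages.values.astype(float))
        hits += r > 0
    return hits / n_seeds


# -------------------------------------------------------------------- GSEA


def gsea_null_pvalues(
    seed: int, n_reps: int = 200, n_genes: int = 200, set_size: int = 15,
    n_perm: int = 500,
) -> np.ndarray:
    """GSEA p-values for randomly placed gene sets on a fixed ranked list
    (should be uniform under the null)."""
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 1, n_genes))[::-1]
    genes = [f"G{i:06d}" for i in range(n_genes)]
    ranked = pd.Series(scores, index=genes)
    pvals = []
    for i in range(n_reps):
        members = rng.choice(genes, set_size, replace=False)
        res = celltype.gsea(
            ranked,
            GeneSet.from_iterable("null", members),
            n_perm=n_perm,
            seed=subseed(seed, f"perm{i}"),
        )
        if res.p is not None:
            pvals.append(res.p)
    return np.array(pvals)
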