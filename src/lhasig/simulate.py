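"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: multi-cohort
negative-binomial count matrices with planted shared "longevity" genes and
sex/batch/library nuisance effects; an age-binned cohort whose planted genes
follow named trajectory archetypes; cell-labelled expression with marker
programs; two-group methylome beta matrices with planted hyper/hypo probes
and an optional global hypomethylation excess; and signature-weighted bulk
mixtures for deconvolution.

The generators are the study conditions for every downstream test: their
defaults describe cohorts of a few dozen cases and controls, moderate
negative-binomial dispersion, and nuisance effects strong enough that
covariate adjustment matters.  All randomness flows from an explicit seed;
the same seed reproduces the same matrices byte for byte.

Gene and probe identifiers are synthetic ("G000001", "cg000001") and carry
no annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from lhasig.containers import CountMatrix

LN2 = np.log(2.0)

DECADE_BINS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79"]

#: Noise-free decade-bin mean profiles on the z scale.  "monotone_up" and
#: "monotone_down" change consistently beyond age 50; "rise_fall" peaks at
#: 60-69 and then declines (a non-monotone trajectory); "late_spike" is flat
#: until an induction confined to 70-79; "flat" has no age trend.
ARCHETYPE_PROFILES = {
    "flat": np.zeros(6),
    "monotone_up": np.array([-1.0, -0.7, -0.3, 0.1, 0.7, 1.4]),
    "monotone_down": np.array([1.0, 0.7, 0.3, -0.1, -0.7, -1.4]),
    "rise_fall": np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 0.3]),
    "late_spike": np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1.0]),
}


def gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:06d}" for i in range(n)], name="gene")


def probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:06d}" for i in range(n)], name="probe")


def archetype_profile(name: str, spike_magnitude: float = 1.0) -> np.ndarray:
    """Noise-free z-scale bin-mean profile for a trajectory archetype."""
    profile = ARCHETYPE_PROFILES[name].copy()
    if name == "late_spike":
        profile = profile * spike_magnitude
    return profile


# ------------------------------------------------------------------ cohorts


@dataclass
class CohortSpec:
    """Sample layout of one cohort: case and control counts plus nuisance
    structure (sex ratio, batch labels)."""

    name: str
    n_case: int = 30
    n_control: int = 30
    sex_ratio: float = 0.5
    batch_labels: Sequence[str] = ("b1", "b2")
    library_labels: Sequence[str] = ("polyA", "total")

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("n_case and n_control must each be >= 2")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Generative parameters for the multi-cohort count simulation.

    Planted shared genes receive a multiplicative ``2**effect`` shift in
    cases of every cohort; cohort-specific genes in one cohort only.  Counts
    are negative binomial with gene-specific log-normal base means and a
    single dispersion, modulated by per-sample library-size factors and
    multiplicative sex/batch/library effects.
    """

    seed: int = 0
    n_genes: int = 2000
    cohorts: Sequence[CohortSpec] = field(
        default_factory=lambda: [CohortSpec("ChM"), CohortSpec("LG"), CohortSpec("LS")]
    )
    planted_shared_up: Sequence[int] = ()
    planted_shared_down: Sequence[int] = ()
    planted_cohort_specific: Mapping[str, Sequence[int]] = field(default_factory=dict)
    effect_log2: float = 1.0
    nb_dispersion: float = 0.1
    base_mean_logscale: tuple = (np.log(100.0), 1.0)
    sex_effect_sd: float = 0.3
    batch_effect_sd: float = 0.3
    library_size_range: tuple = (0.7, 1.3)

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        up, down = set(self.planted_shared_up), set(self.planted_shared_down)
        specific = set()
        for genes in self.planted_cohort_specific.values():
            specific |= set(genes)
        if up & down or up & specific or down & specific:
            raise ValueError("planted gene sets must be disjoint")
        for idx in up | down | specific:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"planted gene index {idx} out of range")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu**2 (Poisson at 0)."""
    if dispersion == 0.0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_multicohort_counts(config: SimulationConfig):
    """Generate one :class:`CountMatrix` per cohort plus a truth table.

    Returns
    -------
    (list of CountMatrix, DataFrame)
        The truth table is indexed by gene id with columns ``role``
        (shared_up / shared_down / cohort_specific / null) and ``effect``
        (the log2 case-vs-control shift).
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    mu, sigma = config.base_mean_logscale
    base_mean = rng.lognormal(mu, sigma, config.n_genes)

    effect = np.zeros(config.n_genes)
    role = np.array(["null"] * config.n_genes, dtype=object)
    effect[list(config.planted_shared_up)] = config.effect_log2
    role[list(config.planted_shared_up)] = "shared_up"
    effect[list(config.planted_shared_down)] = -config.effect_log2
    role[list(config.planted_shared_down)] = "shared_down"
    for genes_i in config.planted_cohort_specific.values():
        role[list(genes_i)] = "cohort_specific"

    # gene-level nuisance coefficients (log2 scale), shared across cohorts
    sex_coef = rng.normal(0.0, config.sex_effect_sd, config.n_genes)

    matrices = []
    for cohort in config.cohorts:
        n = cohort.n_case + cohort.n_control
        group = np.array(["case"] * cohort.n_case + ["control"] * cohort.n_control)
        sex = np.where(rng.random(n) < cohort.sex_ratio, "F", "M")
        batch = np.array([cohort.batch_labels[i % len(cohort.batch_labels)] for i in range(n)])
        library = np.array(
            [
                cohort.library_labels[
                    (i // len(cohort.batch_labels)) % len(cohort.library_labels)
                ]
                for i in range(n)
            ]
        )
        lib_size = rng.uniform(*config.library_size_range, n)

        batch_coef = {
            b: rng.normal(0.0, config.batch_effect_sd, config.n_genes)
            for b in cohort.batch_labels[1:]
        }
        library_coef = {
            l: rng.normal(0.0, config.batch_effect_sd, config.n_genes)
            for l in cohort.library_labels[1:]
        }
        specific = np.zeros(config.n_genes)
        specific[list(config.planted_cohort_specific.get(cohort.name, []))] = (
            config.effect_log2
        )

        log2_shift = np.zeros((config.n_genes, n))
        is_case = (group == "case").astype(float)
        log2_shift += np.outer(effect + specific, is_case)
        log2_shift += np.outer(sex_coef, (sex == "F").astype(float))
        for b, coef in batch_coef.items():
            log2_shift += np.outer(coef, (batch == b).astype(float))
        for l, coef in library_coef.items():
            log2_shift += np.outer(coef, (library == l).astype(float))

        mean = base_mean[:, None] * lib_size[None, :] * 2.0 ** log2_shift
        counts = _nb_draw(rng, mean, config.nb_dispersion)

        samples = pd.Index(
            [f"{cohort.name}_S{i:03d}" for i in range(n)], name="sample"
        )
        metadata = pd.DataFrame(
            {
                "group": group,
                "age": np.where(group == "case", 97, 62),  # nominal ages
                "sex": sex,
                "batch": batch,
                "library": library,
            },
            index=samples,
        )
        matrices.append(
            CountMatrix(
                counts=pd.DataFrame(counts, index=genes, columns=samples),
                metadata=metadata,
            )
        )

    truth = pd.DataFrame({"role": role, "effect": effect}, index=genes)
    return matrices, truth


# --------------------------------------------------------------- age series


@dataclass
class AgeSeriesConfig:
    """Generative parameters for the age-binned cohort (ages 20-79).

    ``archetypes`` maps archetype names to gene index collections; every
    unmentioned gene is flat.  ``amplitude`` converts the z-scale archetype
    profile into log2 fold units.
    """

    seed: int = 0
    n_genes: int = 2000
    n_per_bin: int = 20
    archetypes: Mapping[str, Sequence[int]] = field(default_factory=dict)
    amplitude: float = 1.0
    spike_magnitude: float = 1.0
    noise_sd: float = 0.5
    nb_dispersion: float = 0.05
    base_mean_logscale: tuple = (np.log(100.0), 1.0)
    sex_effect_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_per_bin < 2:
            raise ValueError("need at least 2 samples per decade bin")
        seen = set()
        for name, idx in self.archetypes.items():
            if name not in ARCHETYPE_PROFILES:
                raise ValueError(f"unknown archetype {name!r}")
            idx = set(idx)
            if idx & seen:
                raise ValueError("archetype gene sets must be disjoint")
            if any(not 0 <= i < self.n_genes for i in idx):
                raise ValueError("archetype gene index out of range")
            seen |= idx


def generative_bin_means(config: AgeSeriesConfig) -> pd.DataFrame:
    """Noise-free log2-scale decade-bin mean offsets per gene (genes x 6).

    This is the planted trajectory before count noise; tests read it back to
    verify archetype shapes without Monte-Carlo error.
    """
    profiles = np.zeros((config.n_genes, 6))
    for name, idx in config.archetypes.items():
        profiles[list(idx)] = config.amplitude * archetype_profile(
            name, config.spike_magnitude
        )
    return pd.DataFrame(profiles, index=gene_ids(config.n_genes), columns=DECADE_BINS)


def simulate_age_series(config: AgeSeriesConfig):
    """Generate an age-series :class:`CountMatrix` and its truth table.

    Samples are allocated uniformly to six decade bins (20-29 ... 70-79) with
    ages uniform within each decade.  A planted gene's noise-free log2 mean
    follows its archetype profile scaled by ``amplitude``.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    mu, sigma = config.base_mean_logscale
    base_mean = rng.lognormal(mu, sigma, config.n_genes)

    n = 6 * config.n_per_bin
    bins = np.repeat(np.arange(6), config.n_per_bin)
    ages = 20 + 10 * bins + rng.integers(0, 10, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    sex_coef = rng.normal(0.0, config.sex_effect_sd, config.n_genes)

    profiles = generative_bin_means(config).values  # genes x 6, log2 units
    log2_shift = profiles[:, bins]
    log2_shift = log2_shift + np.outer(sex_coef, (sex == "F").astype(float))
    log2_shift = log2_shift + rng.normal(0.0, config.noise_sd, (config.n_genes, n))

    mean = base_mean[:, None] * 2.0 ** log2_shift
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    samples = pd.Index([f"AGE_S{i:03d}" for i in range(n)], name="sample")
    metadata = pd.DataFrame(
        {"group": "population", "age": ages, "sex": sex, "batch": "b1",
         "library": "polyA"},
        index=samples,
    )

    role = np.array(["null"] * config.n_genes, dtype=object)
    archetype = np.array(["flat"] * config.n_genes, dtype=object)
    for name, idx in config.archetypes.items():
        archetype[list(idx)] = name
        if name == "monotone_up":
            role[list(idx)] = "aging_up"
        elif name == "monotone_down":
            role[list(idx)] = "aging_down"
    truth = pd.DataFrame({"role": role, "archetype": archetype}, index=genes)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples), metadata=metadata
    )
    return cm, truth


# ---------------------------------------------------------------- cell types


@dataclass
class CellTypeConfig:
    """Cell-labelled expression with disjoint marker programs per type and
    optional planted programs elevated in designated groups of types."""

    seed: int = 0
    n_genes: int = 1000
    cell_types: Mapping[str, int] = field(
        default_factory=lambda: {
            "Monocyte": 80, "DC": 40, "NK": 60, "CD8T": 80, "CD4T": 80, "B": 60,
        }
    )
    marker_programs: Mapping[str, Sequence[int]] = field(default_factory=dict)
    marker_effect: float = 2.0
    cluster_programs: Mapping[str, tuple] = field(default_factory=dict)
    # each value: (gene indices, tuple of cell types in which it is elevated)
    cluster_effect: float = 2.0
    base_level: float = 2.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        seen = set()
        for idx in self.marker_programs.values():
            idx = set(idx)
            if idx & seen:
                raise ValueError("marker programs must be disjoint")
            seen |= idx


def simulate_celltype_profiles(config: CellTypeConfig):
    """Generate (cells x genes log expression, cell labels, truth table)."""
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    labels = []
    for ct, n in config.cell_types.items():
        labels += [ct] * n
    labels = pd.Series(
        labels, index=pd.Index([f"C{i:05d}" for i in range(len(labels))], name="cell"),
        name="cell_type",
    )

    base = rng.normal(config.base_level, 0.5, config.n_genes)
    values = np.tile(base, (len(labels), 1))
    for ct, idx in config.marker_programs.items():
        mask = (labels == ct).values
        values[np.ix_(mask, list(idx))] += config.marker_effect
    for _, (idx, types) in config.cluster_programs.items():
        mask = labels.isin(types).values
        values[np.ix_(mask, list(idx))] += config.cluster_effect
    values = values + rng.normal(0.0, config.noise_sd, values.shape)

    expr = pd.DataFrame(values, index=labels.index, columns=genes)

    role = np.array(["null"] * config.n_genes, dtype=object)
    program = np.array([""] * config.n_genes, dtype=object)
    for ct, idx in config.marker_programs.items():
        role[list(idx)] = "marker"
        program[list(idx)] = ct
    for name, (idx, _types) in config.cluster_programs.items():
        role[list(idx)] = "cluster_program"
        program[list(idx)] = name
    truth = pd.DataFrame({"role": role, "program": program}, index=genes)
    return expr, labels, truth


# ----------------------------------------------------------------- methylome


@dataclass
class MethylomeConfig:
    """Two-group 450K-style beta-value simulation.

    Betas are the inverse logit (base 2) of Gaussian M-values.  Planted
    probes shift group B toward a target delta-beta; ``global_hypo_fraction``
    of the remaining probes receive an exponentially distributed negative
    M shift in group B, producing a net negative delta-beta skew (global
    hypomethylation).
    """

    seed: int = 0
    n_probes: int = 2000
    n_a: int = 20
    n_b: int = 20
    m_baseline_sd: float = 2.0
    m_noise_sd: float = 0.5
    planted_hypo: Sequence[int] = ()
    planted_hyper: Sequence[int] = ()
    delta_beta_target: float = 0.2
    global_hypo_fraction: float = 0.0
    global_hypo_scale: float = 0.5
    annotation_genes: int | None = None
    probe_gene_map: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need >= 2 samples per group")
        if set(self.planted_hypo) & set(self.planted_hyper):
            raise ValueError("planted hypo/hyper sets must be disjoint")


def _beta_from_m(m: np.ndarray) -> np.ndarray:
    return expit(m * LN2)


def _m_from_beta(beta: np.ndarray) -> np.ndarray:
    return logit(beta) / LN2


def simulate_methylome(config: MethylomeConfig):
    """Generate (beta A, beta B, probe annotation, truth table).

    The planted shift is computed on the M scale so that the expected
    group-B beta equals the group-A beta plus/minus ``delta_beta_target``
    (clipped away from the 0/1 boundaries).
    """
    rng = np.random.default_rng(config.seed)
    probes = probe_ids(config.n_probes)
    m0 = rng.normal(0.0, config.m_baseline_sd, config.n_probes)
    beta0 = _beta_from_m(m0)

    shift = np.zeros(config.n_probes)
    role = np.array(["null"] * config.n_probes, dtype=object)
    for idx, sign, name in (
        (config.planted_hypo, -1.0, "hypo"),
        (config.planted_hyper, +1.0, "hyper"),
    ):
        idx = list(idx)
        target = np.clip(beta0[idx] + sign * config.delta_beta_target, 0.02, 0.98)
        shift[idx] = _m_from_beta(target) - m0[idx]
        role[idx] = name

    if config.global_hypo_fraction > 0.0:
        free = np.flatnonzero(role == "null")
        n_shift = int(round(config.global_hypo_fraction * len(free)))
        chosen = rng.choice(free, n_shift, replace=False)
        shift[chosen] -= rng.exponential(config.global_hypo_scale, n_shift)
        role[chosen] = "global_hypo"

    m_a = m0[:, None] + rng.normal(0.0, config.m_noise_sd, (config.n_probes, config.n_a))
    m_b = (m0 + shift)[:, None] + rng.normal(
        0.0, config.m_noise_sd, (config.n_probes, config.n_b)
    )
    beta_a = pd.DataFrame(
        _beta_from_m(m_a), index=probes,
        columns=pd.Index([f"A_S{i:03d}" for i in range(config.n_a)], name="sample"),
    )
    beta_b = pd.DataFrame(
        _beta_from_m(m_b), index=probes,
        columns=pd.Index([f"B_S{i:03d}" for i in range(config.n_b)], name="sample"),
    )

    n_annot = config.annotation_genes or config.n_probes
    mapped = [
        config.probe_gene_map.get(i, f"G{i % n_annot:06d}")
        if config.probe_gene_map
        else f"G{i % n_annot:06d}"
        for i in range(config.n_probes)
    ]
    annotation = pd.DataFrame(
        {
            "probe": probes,
            "gene": mapped,
            "chrom": "chr1",
            "pos": 1 + 1000 * np.arange(config.n_probes),  # 1-based positions
        }
    )
    truth = pd.DataFrame({"role": role, "m_shift": shift}, index=probes)
    return beta_a, beta_b, annotation, truth


# ------------------------------------------------------------------ mixtures


def simulate_signature(
    n_genes: int = 200,
    cell_types: Sequence[str] = ("Monocyte", "NK", "CD8T", "CD4T", "B"),
    markers_per_type: int = 20,
    marker_level: float = 80.0,
    background_level: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """LM22-style signature matrix: disjoint high-expression marker blocks on
    a log-normal background (genes x cell types, non-negative)."""
    rng = np.random.default_rng(seed)
    markers_per_type = min(markers_per_type, n_genes // len(cell_types))
    if markers_per_type < 1:
        raise ValueError("need at least one marker gene per cell type")
    sig = rng.lognormal(np.log(background_level), 0.5, (n_genes, len(cell_types)))
    for t in range(len(cell_types)):
        rows = slice(t * markers_per_type, (t + 1) * markers_per_type)
        sig[rows, t] += rng.lognormal(np.log(marker_level), 0.3, markers_per_type)
    return pd.DataFrame(sig, index=gene_ids(n_genes), columns=list(cell_types))


def simulate_mixtures(
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Bulk mixtures ``signature @ proportions.T`` with multiplicative
    log-normal noise.  Returns (bulk genes x samples, truth proportions with
    rows normalized to 1)."""
    rng = np.random.default_rng(seed)
    truth = proportions.div(proportions.sum(axis=1), axis=0)
    bulk = signature.values @ truth.values.T
    if noise_sd > 0:
        bulk = bulk * np.exp(rng.normal(0.0, noise_sd, bulk.shape))
    bulk = pd.DataFrame(bulk, index=signature.index, columns=truth.index)
    return bulk, truth


def random_proportions(
    n_samples: int, cell_types: Sequence[str], seed: int = 0, alpha: float = 2.0
) -> pd.DataFrame:
    """Dirichlet(alpha) cell-type proportions, one row per sample."""
    rng = np.random.default_rng(seed)
    props = rng.dirichlet([alpha] * len(cell_types), n_samples)
    return pd.DataFrame(
        props,
        index=pd.Index([f"MIX_S{i:03d}" for i in range(n_samples)], name="sample"),
        columns=list(cell_types),
    )


# ------------------------------------------------------------- co-expression


@dataclass
class CoexpressionConfig:
    """Planted-block co-expression data for module detection tests.

    Each block of ``block_size`` genes loads on one latent factor; block
    ``age_loaded_block`` (1-based, 0 disables) has its factor tied to sample
    age so the corresponding module eigengene correlates with age.
    """

    seed: int = 0
    n_blocks: int = 3
    block_size: int = 50
    n_noise_genes: int = 100
    n_samples: int = 100
    loading: float = 0.9
    age_loaded_block: int = 1
    age_loading: float = 0.8
    age_range: tuple = (44, 83)


def simulate_coexpression(config: CoexpressionConfig):
    """Generate (expression genes x samples, ages, truth module labels).

    Truth labels are 1..n_blocks for block genes and 0 for noise genes.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_blocks * config.block_size + config.n_noise_genes
    genes = gene_ids(n_genes)
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, config.n_samples)
    age_z = (ages - ages.mean()) / ages.std()

    values = np.empty((n_genes, config.n_samples))
    labels = np.zeros(n_genes, dtype=int)
    lam = config.loading
    for b in range(config.n_blocks):
        if b + 1 == config.age_loaded_block:
            rho = config.age_loading
            factor = rho * age_z + np.sqrt(1 - rho**2) * rng.normal(
                0, 1, config.n_samples
            )
        else:
            factor = rng.normal(0, 1, config.n_samples)
        rows = slice(b * config.block_size, (b + 1) * config.block_size)
        noise = rng.normal(0, 1, (config.block_size, config.n_samples))
        values[rows] = lam * factor[None, :] + np.sqrt(1 - lam**2) * noise
        labels[rows] = b + 1
    values[config.n_blocks * config.block_size :] = rng.normal(
        0, 1, (config.n_noise_genes, config.n_samples)
    )

    samples = pd.Index([f"CX_S{i:03d}" for i in range(config.n_samples)], name="sample")
    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = pd.Series(labels, index=genes, name="module")
    return expr, pd.Series(ages, index=samples, name="age"), truth


# ------------------------------------------------------- regulatory plumbing


def simulate_gene_intervals(
    genes: Sequence[str], seed: int = 0, gene_length: int = 5000, spacing: int = 20000
) -> pd.DataFrame:
    """Gene body coordinates (0-based half-open BED records) on one synthetic
    chromosome, with random strand."""
    rng = np.random.default_rng(seed)
    starts = 10000 + spacing * np.arange(len(genes))
    strand = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + gene_length,
            "name": list(genes),
            "score": 0,
            "strand": strand,
        }
    )


def simulate_peaks(
    promoters: pd.DataFrame,
    bound_genes: Sequence[str],
    seed: int = 0,
    peak_halfwidth: int = 200,
    n_background: int = 50,
    genome_end: int | None = None,
) -> pd.DataFrame:
    """ChIP peak intervals: one peak centred in each bound gene's promoter
    plus background peaks placed in the gaps between promoters."""
    rng = np.random.default_rng(seed)
    bound = set(bound_genes)
    rows = []
    for _, rec in promoters.iterrows():
        if rec["name"] in bound:
            centre = (rec["start"] + rec["end"]) // 2
            rows.append(("chr1", centre - peak_halfwidth, centre + peak_halfwidth))
    end = genome_end or int(promoters["end"].max()) + 100000
    for _ in range(n_background):
        # background peaks live on a separate contig so they bind nothing
        s = int(rng.integers(0, end))
        rows.append(("chr_bg", s, s + 2 * peak_halfwidth))
    return pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[2] for r in rows],
            "name": [f"peak{i:04d}" for i in range(len(rows))],
            "score": 0,
            "strand": ".",
        }
    )


def simulate_stimulus_series(
    genes: Sequence[str],
    reference_gene: str,
    positive_genes: Sequence[str] = (),
    negative_genes: Sequence[str] = (),
    n_conditions: int = 8,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Stimulus-response expression (genes x conditions): positive genes
    track the reference profile, negative genes mirror it, others are
    independent noise."""
    rng = np.random.default_rng(seed)
    ref = np.sin(np.linspace(0, np.pi, n_conditions)) * 2.0
    data = rng.normal(0.0, 1.0, (len(genes), n_conditions))
    df = pd.DataFrame(
        data, index=pd.Index(genes, name="gene"),
        columns=[f"t{i}" for i in range(n_conditions)],
    )
    df.loc[reference_gene] = ref
    for g in positive_genes:
        df.loc[g] = ref + rng.normal(0, noise_sd, n_conditions)
    for g in negative_genes:
        df.loc[g] = -ref + rng.normal(0, noise_sd, n_conditions)
    return df


def simulate_tf_targets(
    tfs: Sequence[str],
    universe: Sequence[str],
    targets_per_tf: int = 50,
    enriched_tfs: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict:
    """TF -> target-gene table; ``enriched_tfs`` forces named TFs to include
    the given genes among their targets."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    table = {}
    for tf in tfs:
        targets = set(rng.choice(universe, targets_per_tf, replace=False))
        if enriched_tfs and tf in enriched_tfs:
            targets |= set(enriched_tfs[tf])
        table[tf] = sorted(targets)
    return table
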