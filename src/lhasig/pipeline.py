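"""End-to-end orchestration of the LHA signature pipeline.

``run_pipeline`` executes simulate -> preprocess -> differential expression
(per cohort) -> consensus -> age patterns -> LHA derivation -> cell-type
analyses -> deconvolution -> co-expression -> methylome -> regulatory,
communicating between stages exclusively through files under the output
directory, and writes a manifest recording the seed, parameters, and a
checksum of every artifact.  Each stage is also runnable standalone against
a directory produced by the earlier stages.

The bundled demo configuration plants, in a universe of a few hundred
genes, shared longevity genes (differentially expressed in every cohort,
not age-trending), aging genes (differentially expressed in every cohort
*and* moving monotonically with age), cell-type programs over the planted
longevity genes, hypomethylated probes on the upregulated longevity genes,
promoter binding sites on the same genes, and signature-weighted bulk
mixtures — so every stage has a ground truth to recover.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lhasig import __version__, age_patterns, celltype, coexpr, consensus
from lhasig import deconvolution, diffexpr, io, methylome, preprocess, regulatory
from lhasig import simulate
from lhasig.containers import GeneSet

STAGES = [
    "simulate", "preprocess", "de", "consensus", "age_patterns", "lha",
    "celltype", "deconvolution", "coexpr", "methylome", "regulatory",
]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "n_genes": 800,
        "n_longevity_up": 40,
        "n_longevity_down": 40,
        "n_aging_up": 40,
        "n_aging_down": 40,
        "effect_log2": 1.0,
        "nb_dispersion": 0.1,
        "cohorts": [
            {"name": "ChM", "n_case": 20, "n_control": 20},
            {"name": "LG", "n_case": 20, "n_control": 20},
            {"name": "LS", "n_case": 20, "n_control": 20},
        ],
        "age_series": {"n_per_bin": 15, "amplitude": 1.0, "noise_sd": 0.5},
        "celltype": {"noise_sd": 0.5},
        "methylome": {
            "n_probes": 800, "n_per_group": 15, "delta_beta": 0.2,
            "global_hypo_fraction": 0.15,
        },
        "mixtures": {"n_samples": 20, "noise_sd": 0.1, "monocyte_shift": 0.15},
        "coexpr": {
            "n_blocks": 3, "block_size": 50, "n_noise_genes": 100,
            "n_samples": 80,
        },
    },
    "preprocess": {"covariates": ["sex", "batch", "library"]},
    "de": {"p_threshold": 0.05, "fc_threshold": 1.2, "use_adjusted": False},
    "consensus": {"n_perm": 2000},
    "age_patterns": {
        "padj_threshold": 0.05, "covariates": ["sex"], "min_corr": 0.7,
        "min_size": 3, "flat_epsilon": 0.05, "spike_delta": 0.5,
    },
    "celltype": {"k": 4, "n_perm": 500, "weight_p": 1.0},
    "deconvolution": {"zero_fraction": 0.5},
    "coexpr": {
        "min_size": 30, "merge_height": 0.1,
        "candidate_powers": [1, 2, 3, 4, 5, 6, 7, 8],
    },
    "methylome": {"d_cut": 0.1, "p_cut": 0.01},
    "regulatory": {
        "upstream": 2000, "downstream": 500, "r_cut": 0.3, "fold_cut": 2.0,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Demo defaults, overlaid with a YAML file and/or a dict of overrides."""
    cfg = default_config()
    if path is not None:
        import yaml

        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    """Stable, independent sub-seed per stage (kept below 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _planted_indices(sim_cfg: dict) -> dict:
    n_lu, n_ld = sim_cfg["n_longevity_up"], sim_cfg["n_longevity_down"]
    n_au, n_ad = sim_cfg["n_aging_up"], sim_cfg["n_aging_down"]
    o = 0
    out = {}
    for key, n in (
        ("longevity_up", n_lu), ("longevity_down", n_ld),
        ("aging_up", n_au), ("aging_down", n_ad),
    ):
        out[key] = list(range(o, o + n))
        o += n
    out["n_planted"] = o
    return out


def _ids(indices) -> list:
    return [f"G{i:06d}" for i in indices]


# ----------------------------------------------------------------- stages


def stage_simulate(cfg: dict, out: Path) -> dict:
    sim = cfg["simulate"]
    seed = cfg["seed"]
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    planted = _planted_indices(sim)

    cohorts = [simulate.CohortSpec(**c) for c in sim["cohorts"]]
    mc_cfg = simulate.SimulationConfig(
        seed=_stage_seed(seed, "multicohort"),
        n_genes=sim["n_genes"],
        cohorts=cohorts,
        planted_shared_up=planted["longevity_up"] + planted["aging_up"],
        planted_shared_down=planted["longevity_down"] + planted["aging_down"],
        effect_log2=sim["effect_log2"],
        nb_dispersion=sim["nb_dispersion"],
    )
    matrices, truth = simulate.simulate_multicohort_counts(mc_cfg)
    for cm, spec in zip(matrices, cohorts):
        io.write_counts_tsv(
            cm, d / f"counts_{spec.name}.tsv", d / f"metadata_{spec.name}.tsv"
        )
    # refine truth roles to separate longevity from aging-confounded genes
    genes = truth.index
    role = truth["role"].copy()
    role.loc[_ids(planted["longevity_up"])] = "longevity_up"
    role.loc[_ids(planted["longevity_down"])] = "longevity_down"
    role.loc[_ids(planted["aging_up"])] = "aging_up"
    role.loc[_ids(planted["aging_down"])] = "aging_down"
    truth["role"] = role
    truth.to_csv(d / "truth_genes.tsv", sep="\t")

    age_cfg = simulate.AgeSeriesConfig(
        seed=_stage_seed(seed, "ages"),
        n_genes=sim["n_genes"],
        archetypes={
            "monotone_up": planted["aging_up"],
            "monotone_down": planted["aging_down"],
        },
        **sim["age_series"],
    )
    age_cm, age_truth = simulate.simulate_age_series(age_cfg)
    io.write_counts_tsv(age_cm, d / "counts_age.tsv", d / "metadata_age.tsv")
    age_truth.to_csv(d / "truth_age.tsv", sep="\t")

    # cell-type programs: planted longevity genes get cell-group structure
    lu, ld = planted["longevity_up"], planted["longevity_down"]
    half_u, half_d = len(lu) // 2, len(ld) // 2
    marker_start = planted["n_planted"]
    types = ["Monocyte", "DC", "NK", "CD8T", "CD4T", "B"]
    marker_programs = {
        t: list(range(marker_start + 15 * i, marker_start + 15 * (i + 1)))
        for i, t in enumerate(types)
    }
    ct_cfg = simulate.CellTypeConfig(
        seed=_stage_seed(seed, "cells"),
        n_genes=sim["n_genes"],
        marker_programs=marker_programs,
        cluster_programs={
            "phagocyte_up": (lu[:half_u], ("Monocyte", "DC")),
            "cytotoxic_up": (lu[half_u:], ("NK", "CD8T")),
            "tcell_down": (ld[:half_d], ("CD4T",)),
            "bcell_down": (ld[half_d:], ("B",)),
        },
        noise_sd=sim["celltype"]["noise_sd"],
    )
    cells, labels, cell_truth = simulate.simulate_celltype_profiles(ct_cfg)
    io.write_matrix_tsv(cells, d / "cells.tsv", index_label="cell")
    labels.to_csv(d / "cell_labels.tsv", sep="\t")
    cell_truth.to_csv(d / "truth_cells.tsv", sep="\t")

    me = sim["methylome"]
    me_cfg = simulate.MethylomeConfig(
        seed=_stage_seed(seed, "methylome"),
        n_probes=me["n_probes"],
        n_a=me["n_per_group"],
        n_b=me["n_per_group"],
        planted_hypo=lu,  # upregulated longevity genes are demethylated
        planted_hyper=ld[:half_d],
        delta_beta_target=me["delta_beta"],
        global_hypo_fraction=me["global_hypo_fraction"],
        annotation_genes=sim["n_genes"],
    )
    beta_a, beta_b, annotation, me_truth = simulate.simulate_methylome(me_cfg)
    io.write_matrix_tsv(beta_a, d / "beta_A.tsv", index_label="probe")
    io.write_matrix_tsv(beta_b, d / "beta_B.tsv", index_label="probe")
    annotation.to_csv(d / "probe_annotation.csv", index=False)
    me_truth.to_csv(d / "truth_methylome.tsv", sep="\t")

    mix = sim["mixtures"]
    signature = simulate.simulate_signature(seed=_stage_seed(seed, "signature"))
    props = simulate.random_proportions(
        mix["n_samples"], signature.columns, seed=_stage_seed(seed, "proportions")
    )
    # plant a monocyte increase in the case half of the mixture samples
    n_case = mix["n_samples"] // 2
    props.iloc[:n_case, props.columns.get_loc("Monocyte")] += mix["monocyte_shift"]
    props = props.div(props.sum(axis=1), axis=0)
    bulk, prop_truth = simulate.simulate_mixtures(
        signature, props, noise_sd=mix["noise_sd"],
        seed=_stage_seed(seed, "mixtures"),
    )
    mix_groups = pd.Series(
        ["case"] * n_case + ["control"] * (mix["n_samples"] - n_case),
        index=props.index, name="group",
    )
    io.write_matrix_tsv(signature, d / "signature.tsv", index_label="gene")
    io.write_matrix_tsv(bulk, d / "bulk_mixtures.tsv", index_label="gene")
    io.write_matrix_tsv(prop_truth, d / "truth_proportions.tsv", index_label="sample")
    mix_groups.to_csv(d / "mixture_groups.tsv", sep="\t")

    cx = sim["coexpr"]
    cx_cfg = simulate.CoexpressionConfig(seed=_stage_seed(seed, "coexpr"), **cx)
    cx_expr, cx_ages, cx_truth = simulate.simulate_coexpression(cx_cfg)
    io.write_matrix_tsv(cx_expr, d / "coexpr_expression.tsv", index_label="gene")
    cx_ages.to_csv(d / "coexpr_ages.tsv", sep="\t")
    cx_truth.to_csv(d / "truth_coexpr.tsv", sep="\t")

    # regulatory inputs: intervals, peaks on upregulated-longevity promoters,
    # insulin stimulus series, TF targets enriched for the same genes
    gene_list = list(genes)
    intervals = simulate.simulate_gene_intervals(
        gene_list, seed=_stage_seed(seed, "intervals")
    )
    promoters = regulatory.promoters_from_genes(
        intervals, cfg["regulatory"]["upstream"], cfg["regulatory"]["downstream"]
    )
    rng = np.random.default_rng(_stage_seed(seed, "peaks"))
    bound = set(_ids(lu)) | set(
        rng.choice(
            [g for g in gene_list if g not in set(_ids(lu))], 100, replace=False
        )
    )
    peaks = simulate.simulate_peaks(
        promoters, sorted(bound), seed=_stage_seed(seed, "peaks")
    )
    io.write_bed(intervals, d / "genes.bed")
    io.write_bed(peaks, d / "peaks.bed")
    pd.Series(sorted(bound), name="gene").to_csv(d / "truth_bound_genes.tsv",
                                                 sep="\t", index=False)

    ref = "INSR_REF"
    series = simulate.simulate_stimulus_series(
        gene_list + [ref], ref,
        positive_genes=_ids(lu[:half_u]),
        negative_genes=_ids(ld[:half_d]),
        seed=_stage_seed(seed, "stimulus"),
    )
    io.write_matrix_tsv(series, d / "stimulus_series.tsv", index_label="gene")

    tfs = [f"TF{i:03d}" for i in range(30)]
    tf_table = simulate.simulate_tf_targets(
        tfs, gene_list, targets_per_tf=40,
        enriched_tfs={t: _ids(lu[:half_u]) for t in tfs[:5]},
        seed=_stage_seed(seed, "tf"),
    )
    io.write_json(tf_table, d / "tf_targets.json")

    io.write_json(
        {
            "cohorts": [c["name"] for c in sim["cohorts"]],
            "planted": {k: v for k, v in planted.items() if k != "n_planted"},
        },
        d / "simulate_summary.json",
    )
    return {"cohorts": [c["name"] for c in sim["cohorts"]]}


def _cohort_names(out: Path) -> list:
    return io.read_json(out / "simulate" / "simulate_summary.json")["cohorts"]


def stage_preprocess(cfg: dict, out: Path) -> dict:
    d = out / "preprocess"
    d.mkdir(parents=True, exist_ok=True)
    sdir = out / "simulate"
    summary = {}
    for name in _cohort_names(out) + ["age"]:
        cm = io.read_counts_tsv(
            sdir / f"counts_{name}.tsv", sdir / f"metadata_{name}.tsv"
        )
        em = preprocess.log_normalize(cm)
        covars = [
            c for c in cfg["preprocess"]["covariates"]
            if cm.metadata[c].nunique() > 1
        ]
        if covars:
            em = preprocess.remove_covariate_effects(em, covars)
        io.write_expression(em, d / f"expr_{name}.tsv", d / f"provenance_{name}.json")
        cm.metadata.to_csv(d / f"metadata_{name}.tsv", sep="\t", index_label="sample")
        summary[name] = {"n_genes": em.values.shape[0], "covariates": covars}
    return summary


def _read_expr(out: Path, name: str):
    return io.read_expression(
        out / "preprocess" / f"expr_{name}.tsv",
        out / "preprocess" / f"metadata_{name}.tsv",
        out / "preprocess" / f"provenance_{name}.json",
    )


def stage_de(cfg: dict, out: Path) -> dict:
    d = out / "de"
    d.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name in _cohort_names(out):
        em = _read_expr(out, name)
        table = diffexpr.de_two_group(em)
        io.write_matrix_tsv(table, d / f"de_{name}.tsv", index_label="gene")
        up, down = diffexpr.call_degs(
            table,
            p_threshold=cfg["de"]["p_threshold"],
            fc_threshold=cfg["de"]["fc_threshold"],
            use_adjusted=cfg["de"]["use_adjusted"],
            name_prefix=name,
        )
        io.write_gmt([up, down], d / f"degs_{name}.gmt")
        summary[name] = {"n_up": len(up), "n_down": len(down)}
    return summary


def stage_consensus(cfg: dict, out: Path) -> dict:
    d = out / "consensus"
    d.mkdir(parents=True, exist_ok=True)
    names = _cohort_names(out)
    sets = {n: io.read_gmt(out / "de" / f"degs_{n}.gmt") for n in names}
    universe = None
    for n in names:
        genes = set(io.read_matrix_tsv(out / "de" / f"de_{n}.tsv").index)
        universe = genes if universe is None else universe & genes
    result = {}
    for direction, pos in (("up", 0), ("down", 1)):
        cohort_sets = [sets[n][pos] for n in names]
        cdeg = consensus.intersect_sets(
            cohort_sets, direction, name=f"cDEG_{direction}"
        )
        null = consensus.permutation_overlap_null(
            len(universe),
            [len(s) for s in cohort_sets],
            n_perm=cfg["consensus"]["n_perm"],
            seed=_stage_seed(cfg["seed"], f"consensus_{direction}"),
            observed=len(cdeg),
        )
        result[direction] = {
            "observed": len(cdeg),
            "null_mean": null.null_mean,
            "null_sd": null.null_sd,
            "analytic_expectation": null.analytic_expectation,
            "empirical_p": null.empirical_p,
            "set_sizes": [len(s) for s in cohort_sets],
            "universe": len(universe),
        }
        io.write_gmt([cdeg], d / f"cdeg_{direction}.gmt")
    io.write_json(result, d / "overlap_null.json")
    return result


def stage_age_patterns(cfg: dict, out: Path) -> dict:
    d = out / "age_patterns"
    d.mkdir(parents=True, exist_ok=True)
    ap = cfg["age_patterns"]
    em = _read_expr(out, "age")
    assoc = age_patterns.age_association_test(em, covariates=ap["covariates"])
    io.write_matrix_tsv(assoc, d / "age_association.tsv", index_label="gene")
    significant = assoc.index[assoc["padj"] < ap["padj_threshold"]]
    profiles = age_patterns.bin_profiles(em).loc[significant]
    io.write_matrix_tsv(profiles, d / "bin_profiles.tsv", index_label="gene")
    groups = age_patterns.cluster_patterns(
        profiles, min_corr=ap["min_corr"], min_size=ap["min_size"]
    )
    aging_up, aging_down = age_patterns.select_age_groups(
        groups,
        flat_epsilon=ap["flat_epsilon"],
        spike_delta=ap["spike_delta"],
        min_size=ap["min_size"],
    )
    io.write_gmt([aging_up, aging_down], d / "aging_sets.gmt")
    report = [
        {
            "group_id": g.group_id,
            "size": len(g.members),
            "slope_value": g.slope_value,
            "selected": g.selected,
            "direction": g.direction,
            "reason": g.reason,
            "centroid": [round(float(x), 6) for x in g.centroid],
        }
        for g in groups
    ]
    io.write_json(report, d / "selection_report.json")
    return {
        "n_significant": int(len(significant)),
        "n_groups": len(groups),
        "n_selected": sum(g.selected for g in groups),
        "n_aging_up": len(aging_up),
        "n_aging_down": len(aging_down),
    }


def stage_lha(cfg: dict, out: Path) -> dict:
    d = out / "lha"
    d.mkdir(parents=True, exist_ok=True)
    cdeg_up = io.read_gmt(out / "consensus" / "cdeg_up.gmt")[0]
    cdeg_down = io.read_gmt(out / "consensus" / "cdeg_down.gmt")[0]
    aging = io.read_gmt(out / "age_patterns" / "aging_sets.gmt")
    result = age_patterns.derive_lha(cdeg_up, cdeg_down, aging)
    io.write_gmt([result.lha_up, result.lha_down], d / "lha_sets.gmt")
    io.write_json(result.provenance, d / "removal_provenance.json")
    return {
        "n_lha_up": len(result.lha_up),
        "n_lha_down": len(result.lha_down),
        "n_removed": len(result.removed_aging),
    }


def stage_celltype(cfg: dict, out: Path) -> dict:
    d = out / "celltype"
    d.mkdir(parents=True, exist_ok=True)
    cells = io.read_matrix_tsv(out / "simulate" / "cells.tsv")
    labels = pd.read_csv(
        out / "simulate" / "cell_labels.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    lha_sets = io.read_gmt(out / "lha" / "lha_sets.gmt")
    lha_up, lha_down = lha_sets[0], lha_sets[1]
    lha_all = sorted(lha_up.members | lha_down.members)

    scores = celltype.gene_cell_scores(cells, labels)
    io.write_matrix_tsv(scores, d / "gene_cell_scores.tsv", index_label="gene")

    present = [g for g in lha_all if g in scores.index]
    clusters = celltype.cluster_gene_scores(
        scores.loc[present], k=cfg["celltype"]["k"],
        seed=_stage_seed(cfg["seed"], "kmeans"),
    )
    clusters.to_csv(d / "lha_clusters.tsv", sep="\t")

    enrichment = {}
    for target in sorted(labels.unique()):
        ranked = celltype.rank_genes_for_celltype(cells, labels, target)
        res = celltype.gsea(
            ranked, lha_up,
            weight_p=cfg["celltype"]["weight_p"],
            n_perm=cfg["celltype"]["n_perm"],
            seed=_stage_seed(cfg["seed"], f"gsea_{target}"),
        )
        enrichment[target] = {"es": res.es, "nes": res.nes, "p": res.p}
    io.write_json(enrichment, d / "lha_up_enrichment.json")

    # per-cell signature score of the upregulated LHA set, ANOVA across types
    score = celltype.signature_score(cells.T, lha_up)
    F, p = celltype.anova_across_groups(score, labels)
    io.write_json({"F": F, "p": p}, d / "signature_anova.json")
    return {"enrichment": enrichment, "anova_F": F, "anova_p": p}


def stage_deconvolution(cfg: dict, out: Path) -> dict:
    d = out / "deconvolution"
    d.mkdir(parents=True, exist_ok=True)
    signature = io.read_matrix_tsv(out / "simulate" / "signature.tsv")
    bulk = io.read_matrix_tsv(out / "simulate" / "bulk_mixtures.tsv")
    groups = pd.read_csv(
        out / "simulate" / "mixture_groups.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    estimate = deconvolution.nnls_proportions(bulk, signature)
    io.write_matrix_tsv(
        estimate.proportions, d / "proportions.tsv", index_label="sample"
    )
    filtered = deconvolution.filter_celltypes(
        estimate, cfg["deconvolution"]["zero_fraction"]
    )
    io.write_matrix_tsv(
        filtered.proportions, d / "proportions_filtered.tsv", index_label="sample"
    )
    table = deconvolution.compare_proportions(filtered, groups)
    table.to_csv(d / "group_comparison.tsv", sep="\t", index=False)
    truth = io.read_matrix_tsv(out / "simulate" / "truth_proportions.tsv")
    mae = float(
        np.abs(
            estimate.proportions[truth.columns].values - truth.values
        ).mean()
    )
    io.write_json({"mae_vs_truth": mae, "meta": estimate.meta}, d / "summary.json")
    return {"mae_vs_truth": mae}


def stage_coexpr(cfg: dict, out: Path) -> dict:
    d = out / "coexpr"
    d.mkdir(parents=True, exist_ok=True)
    expr = io.read_matrix_tsv(out / "simulate" / "coexpr_expression.tsv")
    ages = pd.read_csv(
        out / "simulate" / "coexpr_ages.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    power, fit = coexpr.pick_soft_threshold(
        expr, cfg["coexpr"]["candidate_powers"]
    )
    fit.to_csv(d / "soft_threshold_fit.tsv", sep="\t", index=False)
    adj = coexpr.adjacency(expr, power)
    tom = coexpr.tom_similarity(adj)
    modules = coexpr.detect_modules(
        1.0 - tom, expr,
        min_size=cfg["coexpr"]["min_size"],
        merge_height=cfg["coexpr"]["merge_height"],
        soft_power=power,
    )
    modules.labels.to_csv(d / "modules.tsv", sep="\t")
    eig_frames = {}
    for mid in sorted(set(modules.labels) - {0}):
        eig = coexpr.module_eigengene(
            expr, modules.labels.index[modules.labels == mid], mid
        )
        eig_frames[f"ME{mid}"] = eig.scores
    eigengenes = pd.DataFrame(eig_frames)
    io.write_matrix_tsv(eigengenes, d / "eigengenes.tsv", index_label="sample")
    trait = coexpr.correlate_with_trait(eigengenes, ages)
    trait.to_csv(d / "module_age_correlation.tsv", sep="\t", index=False)
    return {
        "soft_power": power,
        "module_sizes": modules.sizes,
        "age_correlations": {
            row["module"]: round(float(row["r"]), 4) for _, row in trait.iterrows()
        },
    }


def stage_methylome(cfg: dict, out: Path) -> dict:
    d = out / "methylome"
    d.mkdir(parents=True, exist_ok=True)
    beta_a = io.read_matrix_tsv(out / "simulate" / "beta_A.tsv")
    beta_b = io.read_matrix_tsv(out / "simulate" / "beta_B.tsv")
    annotation = pd.read_csv(out / "simulate" / "probe_annotation.csv")
    db = methylome.delta_beta(beta_a, beta_b)
    g1 = methylome.skewness(db.values)
    dmps = methylome.call_dmps(
        beta_a, beta_b, d_cut=cfg["methylome"]["d_cut"],
        p_cut=cfg["methylome"]["p_cut"],
    )
    io.write_matrix_tsv(dmps, d / "dmps.tsv", index_label="probe")
    hyper, hypo, info = methylome.map_probes_to_genes(dmps, annotation)
    io.write_gmt([hyper, hypo], d / "methylation_sets.gmt")
    clusters = pd.read_csv(
        out / "celltype" / "lha_clusters.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    cluster_sets = {
        f"cluster_{c}": set(clusters.index[clusters == c])
        for c in sorted(clusters.unique())
    }
    universe = set(annotation["gene"])
    table = methylome.classify_lha_methylation(hyper, hypo, cluster_sets, universe)
    table.to_csv(d / "lha_methylation.tsv", sep="\t", index=False)
    summary = {
        "skewness": g1,
        "n_hyper": int((dmps["call"] == "hyper").sum()),
        "n_hypo": int((dmps["call"] == "hypo").sum()),
        "mapping": info,
    }
    io.write_json(summary, d / "summary.json")
    return summary


def stage_regulatory(cfg: dict, out: Path) -> dict:
    d = out / "regulatory"
    d.mkdir(parents=True, exist_ok=True)
    rc = cfg["regulatory"]
    genes = io.read_bed(out / "simulate" / "genes.bed")
    peaks = io.read_bed(out / "simulate" / "peaks.bed")
    promoters = regulatory.promoters_from_genes(
        genes, upstream=rc["upstream"], downstream=rc["downstream"]
    )
    io.write_bed(promoters, d / "promoters.bed")
    overlaps = regulatory.interval_overlap(promoters, peaks)
    overlaps.to_csv(d / "promoter_peak_overlap.tsv", sep="\t", index=False)
    bound = GeneSet.from_iterable("bound", overlaps["a_name"].unique())

    clusters = pd.read_csv(
        out / "celltype" / "lha_clusters.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    cluster_sets = {
        f"cluster_{c}": set(clusters.index[clusters == c])
        for c in sorted(clusters.unique())
    }
    universe = set(genes["name"])
    ratios = regulatory.binding_ratio_per_cluster(cluster_sets, bound, universe)
    ratios.to_csv(d / "binding_ratios.tsv", sep="\t", index=False)

    series = io.read_matrix_tsv(out / "simulate" / "stimulus_series.tsv")
    lha_sets = io.read_gmt(out / "lha" / "lha_sets.gmt")
    lha_all = sorted(lha_sets[0].members | lha_sets[1].members)
    corr = regulatory.stimulus_correlation(
        series, "INSR_REF",
        [g for g in lha_all if g in series.index],
        r_cut=rc["r_cut"],
    )
    corr.to_csv(d / "stimulus_correlation.tsv", sep="\t")

    tf_table = io.read_json(out / "simulate" / "tf_targets.json")
    enr = regulatory.tf_target_enrichment(tf_table, lha_sets[0], universe)
    enr.to_csv(d / "tf_enrichment.tsv", sep="\t", index=False)

    scores = io.read_matrix_tsv(out / "celltype" / "gene_cell_scores.tsv")
    marker_summary = io.read_json(out / "simulate" / "simulate_summary.json")
    specific = regulatory.tf_specificity_filter(
        scores, ("Monocyte", "DC"), fold_cut=rc["fold_cut"]
    )
    pd.Series(specific, name="gene").to_csv(
        d / "phagocyte_specific_genes.tsv", sep="\t", index=False
    )
    return {
        "n_bound_genes": len(bound),
        "binding_ratios": {
            row["cluster"]: round(float(row["ratio"]), 4)
            if np.isfinite(row["ratio"]) else None
            for _, row in ratios.iterrows()
        },
        "n_enriched_tfs": int((enr["padj"] < 0.05).sum()),
        "n_phagocyte_specific": len(specific),
        "cohorts": marker_summary["cohorts"],
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "de": stage_de,
    "consensus": stage_consensus,
    "age_patterns": stage_age_patterns,
    "lha": stage_lha,
    "celltype": stage_celltype,
    "deconvolution": stage_deconvolution,
    "coexpr": stage_coexpr,
    "methylome": stage_methylome,
    "regulatory": stage_regulatory,
}


def _checksum_tree(out: Path) -> dict:
    sums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            sums[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return sums


def run_stage(name: str, cfg: dict, out) -> dict:
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r} (choose from {STAGES})")
    return _STAGE_FUNCS[name](cfg, Path(out))


def run_pipeline(cfg: dict | None = None, out=".", stages=None) -> dict:
    """Run the pipeline end to end; returns (and writes) the manifest."""
    cfg = cfg or default_config()
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stage_list = stages or STAGES
    manifest: dict = {
        "package": "lhasig",
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "stages": {},
    }
    for name in stage_list:
        try:
            manifest["stages"][name] = run_stage(name, cfg, out)
        except Exception as exc:
            manifest["error"] = {"stage": name, "message": str(exc)}
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True, default=io._jsonable)
            )
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest["checksums"] = _checksum_tree(out)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=io._jsonable) + "\n"
    )
    return manifest
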