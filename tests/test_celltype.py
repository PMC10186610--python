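"""Ranking, GSEA running sum, gene scoring, clustering, ORA, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from lhasig import celltype, simulate
from lhasig.containers import GeneSet
from lhasig.simulate import CellTypeConfig


def brute_force_es(hit_positions, n, scores=None, weight_p=0.0):
    """Independent running-sum oracle: explicit loop, signed max deviation."""
    hits = set(hit_positions)
    m = len(hits)
    if scores is None:
        scores = np.zeros(n)
    weights = [abs(scores[i]) ** weight_p for i in range(n)]
    hit_total = sum(weights[i] for i in hits) or float(m)
    running, best = 0.0, 0.0
    for i in range(n):
        if i in hits:
            running += (weights[i] / hit_total) if sum(
                weights[j] for j in hits
            ) > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 1, n))[::-1]
    return pd.Series(scores, index=[f"G{i:03d}" for i in range(n)])


class TestRanking:
    @pytest.fixture
    def two_type_expr(self):
        cells = pd.Index([f"C{i}" for i in range(6)], name="cell")
        expr = pd.DataFrame(
            [[5, 0, 1], [5, 0, 1], [5, 0, 1], [0, 0, 1], [0, 0, 1], [0, 0, 1]],
            index=cells, columns=["marker", "zero", "uniform"], dtype=float,
        )
        labels = pd.Series(["T"] * 3 + ["R"] * 3, index=cells)
        return expr, labels

    def test_exclusive_marker_ranks_first(self, two_type_expr):
        expr, labels = two_type_expr
        ranked = celltype.rank_genes_for_celltype(expr, labels, "T")
        assert ranked.index[0] == "marker"

    def test_uniform_gene_scores_zero(self, two_type_expr):
        expr, labels = two_type_expr
        ranked = celltype.rank_genes_for_celltype(expr, labels, "T")
        assert ranked["uniform"] == 0.0

    def test_two_type_symmetry(self, two_type_expr):
        expr, labels = two_type_expr
        a = celltype.rank_genes_for_celltype(expr, labels, "T")
        b = celltype.rank_genes_for_celltype(expr, labels, "R")
        np.testing.assert_allclose(a.sort_index(), -b.sort_index())


class TestGsea:
    def test_top_k_set_matches_oracle(self):
        ranked = _ranked(20)
        for k in (1, 3, 7):
            gs = GeneSet.from_iterable("top", ranked.index[:k])
            res = celltype.gsea(ranked, gs, weight_p=0.0, n_perm=100, seed=0)
            assert res.es == pytest.approx(brute_force_es(range(k), 20))

    def test_reversed_list_preserves_es_magnitude(self):
        ranked = _ranked(30, seed=3)
        gs = GeneSet.from_iterable("s", ranked.index[5:12])
        fwd = celltype.gsea(ranked, gs, weight_p=0.0, n_perm=100, seed=0)
        rev = celltype.gsea(ranked[::-1], gs, weight_p=0.0, n_perm=100, seed=0)
        assert abs(fwd.es) == pytest.approx(abs(rev.es))

    def test_weighted_es_matches_oracle_random_sets(self):
        rng = np.random.default_rng(5)
        ranked = _ranked(50, seed=5)
        for _ in range(30):
            members = rng.choice(ranked.index, rng.integers(2, 20), replace=False)
            gs = GeneSet.from_iterable("s", members)
            res = celltype.gsea(ranked, gs, weight_p=1.0, n_perm=100, seed=0)
            positions = [i for i, g in enumerate(ranked.index) if g in gs.members]
            oracle = brute_force_es(positions, 50, ranked.values, weight_p=1.0)
            assert res.es == pytest.approx(oracle, abs=1e-12)

    def test_es_bounded_and_leading_edge_in_set(self):
        ranked = _ranked(40, seed=9)
        gs = GeneSet.from_iterable("s", ranked.index[::5])
        res = celltype.gsea(ranked, gs, n_perm=200, seed=1)
        assert -1.0 <= res.es <= 1.0
        assert set(res.leading_edge) <= gs.members

    @pytest.mark.parametrize("members", [[], None])
    def test_degenerate_sets_rejected(self, members):
        ranked = _ranked(10)
        members = list(ranked.index) if members is None else members
        with pytest.raises(ValueError):
            celltype.gsea(ranked, GeneSet.from_iterable("s", members))


class TestGeneCellScores:
    def test_uniform_gene_scores_zero_everywhere(self):
        cells = pd.Index([f"C{i}" for i in range(8)], name="cell")
        expr = pd.DataFrame({"flat": 3.0, "var": np.arange(8.0)}, index=cells)
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=cells)
        scores = celltype.gene_cell_scores(expr, labels)
        np.testing.assert_allclose(scores.loc["flat"], 0.0)

    def test_type_specific_gene_peaks_in_its_type(self):
        cfg = CellTypeConfig(
            seed=0, n_genes=50, cell_types={"Monocyte": 30, "B": 30, "NK": 30},
            marker_programs={"Monocyte": range(10)}, noise_sd=0.1,
        )
        expr, labels, _ = simulate.simulate_celltype_profiles(cfg)
        scores = celltype.gene_cell_scores(expr, labels)
        assert (scores.iloc[:10].idxmax(axis=1) == "Monocyte").all()

    def test_size_weighted_mean_is_zero(self, rng):
        cells = pd.Index([f"C{i}" for i in range(10)], name="cell")
        expr = pd.DataFrame(rng.normal(0, 1, (10, 5)), index=cells)
        labels = pd.Series(["A"] * 7 + ["B"] * 3, index=cells)
        scores = celltype.gene_cell_scores(expr, labels)
        weighted = 0.7 * scores["A"] + 0.3 * scores["B"]
        np.testing.assert_allclose(weighted, 0.0, atol=1e-10)


class TestClusterGeneScores:
    def test_two_planted_programs_separate(self):
        scores = pd.DataFrame(
            np.vstack([np.tile([3.0, 0.0], (10, 1)), np.tile([0.0, 3.0], (10, 1))]),
            index=simulate.gene_ids(20), columns=["A", "B"],
        )
        labels = celltype.cluster_gene_scores(scores, k=2, seed=0)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_single_cluster(self, rng):
        scores = pd.DataFrame(rng.normal(0, 1, (15, 3)), index=simulate.gene_ids(15))
        labels = celltype.cluster_gene_scores(scores, k=1, seed=0)
        assert (labels == 1).all()

    def test_four_program_recovery(self):
        # four programs over type groups (as in the LHA cluster analysis)
        aris = []
        for seed in range(10):
            cfg = CellTypeConfig(
                seed=seed, n_genes=120,
                cell_types={"Monocyte": 40, "DC": 20, "NK": 30, "CD8T": 40,
                            "CD4T": 40, "B": 30},
                cluster_programs={
                    "p1": (range(0, 30), ("Monocyte", "DC")),
                    "p2": (range(30, 60), ("NK", "CD8T")),
                    "p3": (range(60, 90), ("CD4T",)),
                    "p4": (range(90, 120), ("B",)),
                },
                noise_sd=0.3,
            )
            expr, labels, truth = simulate.simulate_celltype_profiles(cfg)
            scores = celltype.gene_cell_scores(expr, labels)
            clusters = celltype.cluster_gene_scores(scores, k=4, seed=seed)
            aris.append(adjusted_rand_score(truth["program"].values, clusters.values))
        assert np.mean(aris) >= 0.9


class TestSignatureScore:
    def test_constant_genes_score_zero(self):
        expr = pd.DataFrame(
            np.full((4, 6), 5.0), index=simulate.gene_ids(4),
            columns=[f"S{i}" for i in range(6)],
        )
        gs = GeneSet.from_iterable("s", expr.index)
        np.testing.assert_allclose(celltype.signature_score(expr, gs), 0.0)

    def test_union_score_is_mean_of_halves(self, rng):
        expr = pd.DataFrame(
            rng.normal(0, 1, (20, 8)), index=simulate.gene_ids(20),
            columns=[f"S{i}" for i in range(8)],
        )
        a = GeneSet.from_iterable("a", expr.index[:10])
        b = GeneSet.from_iterable("b", expr.index[10:])
        ab = GeneSet.from_iterable("ab", expr.index)
        expected = (
            celltype.signature_score(expr, a) + celltype.signature_score(expr, b)
        ) / 2
        np.testing.assert_allclose(
            celltype.signature_score(expr, ab), expected, atol=1e-12
        )

    def test_planted_shift_reflected_in_score_difference(self, rng):
        base = rng.normal(0, 0.01, (10, 10))
        z_unit = np.zeros((10, 10))
        z_unit[:, 5:] = 1.0
        expr = pd.DataFrame(
            base + z_unit, index=simulate.gene_ids(10),
            columns=[f"S{i}" for i in range(10)],
        )
        gs = GeneSet.from_iterable("s", expr.index)
        score = celltype.signature_score(expr, gs)
        assert score[5:].mean() - score[:5].mean() > 1.5  # ~2 z after scaling


class TestOraAnova:
    def test_ora_trivial_cases(self):
        universe = [f"G{i}" for i in range(20)]
        query = GeneSet.from_iterable("q", universe[:5])
        table = celltype.ora_hypergeometric(
            query, {"all": universe, "disjoint": universe[10:]}, universe
        )
        assert table.set_index("pathway").loc["all", "p"] == 1.0
        assert table.set_index("pathway").loc["disjoint", "p"] == 1.0

    def test_enriched_pathway_detected(self):
        universe = [f"G{i}" for i in range(100)]
        query = GeneSet.from_iterable("q", universe[:10])
        table = celltype.ora_hypergeometric(
            query, {"hit": universe[:10], "bg": universe[50:]}, universe
        ).set_index("pathway")
        assert table.loc["hit", "p"] < 1e-6
        assert table.loc["hit", "padj"] <= 2 * table.loc["hit", "p"]

    def test_anova_two_groups_equals_t_test(self, rng):
        scores = pd.Series(rng.normal(0, 1, 20), index=[f"S{i}" for i in range(20)])
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=scores.index)
        F, p = celltype.anova_across_groups(scores, groups)
        t, p_t = stats.ttest_ind(scores[:10], scores[10:], equal_var=True)
        assert F == pytest.approx(t**2)
        assert p == pytest.approx(p_t)

    def test_anova_null_calibrated(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            scores = pd.Series(rng.normal(0, 1, 30), index=range(30))
            groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                               index=scores.index)
            pvals.append(celltype.anova_across_groups(scores, groups)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
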