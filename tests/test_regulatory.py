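"""Stimulus correlation, promoter windows, interval sweep, TF analyses."""

import numpy as np
import pandas as pd
import pytest

from lhasig import io, regulatory, simulate
from lhasig.containers import GeneSet


def _intervals(records):
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


class TestStimulusCorrelation:
    @pytest.fixture
    def series(self):
        t = np.linspace(0, np.pi, 8)
        ref = np.sin(t)
        return pd.DataFrame(
            {"t%d" % i: col for i, col in enumerate(
                np.vstack([ref, ref * 2 + 1, -ref, np.full(8, 3.0)]).T
            )},
            index=["REF", "POS", "NEG", "CONST"],
        )

    def test_reference_correlates_perfectly_with_itself(self, series):
        out = regulatory.stimulus_correlation(series, "REF", ["POS"])
        assert out.loc["POS", "r"] == pytest.approx(1.0)
        assert out.loc["POS", "class"] == "positive"

    def test_mirrored_profile_negative(self, series):
        out = regulatory.stimulus_correlation(series, "REF", ["NEG"])
        assert out.loc["NEG", "r"] == pytest.approx(-1.0)
        assert out.loc["NEG", "class"] == "negative"

    def test_constant_profile_flagged_degenerate(self, series):
        out = regulatory.stimulus_correlation(series, "REF", ["CONST"])
        assert out.loc["CONST", "class"] == "none"
        assert bool(out.loc["CONST", "degenerate"])

    def test_missing_reference_rejected(self, series):
        with pytest.raises(ValueError):
            regulatory.stimulus_correlation(series, "ABSENT")


class TestPromoters:
    def test_plus_strand_window(self):
        genes = _intervals([("chr1", 10000, 15000, "GA", 0, "+")])
        prom = regulatory.promoters_from_genes(genes, 2000, 500)
        assert (prom["start"].iloc[0], prom["end"].iloc[0]) == (8000, 10500)

    def test_minus_strand_mirrors(self):
        genes = _intervals([("chr1", 5000, 10000, "GB", 0, "-")])
        prom = regulatory.promoters_from_genes(genes, 2000, 500)
        assert (prom["start"].iloc[0], prom["end"].iloc[0]) == (9500, 12000)

    def test_clipped_at_chromosome_start(self):
        genes = _intervals([("chr1", 100, 4000, "GC", 0, "+")])
        prom = regulatory.promoters_from_genes(genes, 2000, 500)
        assert (prom["start"].iloc[0], prom["end"].iloc[0]) == (0, 600)


class TestIntervalOverlap:
    @staticmethod
    def brute_force(a, b):
        pairs = []
        for i, ra in a.iterrows():
            for j, rb in b.iterrows():
                if (
                    ra["chrom"] == rb["chrom"]
                    and ra["start"] < rb["end"]
                    and rb["start"] < ra["end"]
                ):
                    pairs.append((i, j))
        return sorted(pairs)

    def test_half_open_adjacency_is_not_overlap(self):
        a = _intervals([("chr1", 0, 10, "a", 0, "+")])
        b = _intervals([("chr1", 10, 20, "b", 0, "+")])
        assert len(regulatory.interval_overlap(a, b)) == 0

    def test_one_base_overlap_detected(self):
        a = _intervals([("chr1", 0, 10, "a", 0, "+")])
        b = _intervals([("chr1", 9, 20, "b", 0, "+")])
        out = regulatory.interval_overlap(a, b)
        assert list(zip(out["a_index"], out["b_index"])) == [(0, 0)]

    def test_matches_brute_force_on_random_sets(self, rng):
        for trial in range(100):
            n_a, n_b = rng.integers(5, 30, 2)
            chroms = ["chr1", "chr2"]
            a = _intervals(
                [
                    (
                        chroms[rng.integers(2)], s, s + rng.integers(1, 50),
                        f"a{i}", 0, "+",
                    )
                    for i, s in enumerate(rng.integers(0, 300, n_a))
                ]
            )
            b = _intervals(
                [
                    (
                        chroms[rng.integers(2)], s, s + rng.integers(1, 50),
                        f"b{i}", 0, "+",
                    )
                    for i, s in enumerate(rng.integers(0, 300, n_b))
                ]
            )
            out = regulatory.interval_overlap(a, b)
            assert (
                sorted(zip(out["a_index"], out["b_index"]))
                == self.brute_force(a, b)
            )

    def test_large_instance_against_oracle(self, rng):
        starts = rng.integers(0, 100000, 500)
        a = _intervals(
            [("chr1", s, s + int(rng.integers(50, 500)), f"a{i}", 0, "+")
             for i, s in enumerate(starts[:250])]
        )
        b = _intervals(
            [("chr1", s, s + int(rng.integers(50, 500)), f"b{i}", 0, "+")
             for i, s in enumerate(starts[250:])]
        )
        out = regulatory.interval_overlap(a, b)
        assert (
            sorted(zip(out["a_index"], out["b_index"])) == self.brute_force(a, b)
        )

    def test_bed_round_trip(self, rng, tmp_path):
        iv = _intervals(
            [("chr1", int(s), int(s) + 100, f"x{i}", 0, "+")
             for i, s in enumerate(rng.integers(0, 1000, 20))]
        )
        io.write_bed(iv, tmp_path / "x.bed")
        back = io.read_bed(tmp_path / "x.bed")
        pd.testing.assert_frame_equal(
            back[["chrom", "start", "end", "name"]],
            iv[["chrom", "start", "end", "name"]],
        )


class TestBindingRatios:
    def test_fully_bound_cluster(self):
        universe = [f"G{i}" for i in range(20)]
        bound = GeneSet.from_iterable("bound", universe[:10])
        table = regulatory.binding_ratio_per_cluster(
            {"c1": universe[:5], "c2": universe[15:]}, bound, universe
        ).set_index("cluster")
        assert table.loc["c1", "ratio"] == 1.0
        assert table.loc["c2", "ratio"] == 0.0

    def test_duplicate_peaks_do_not_inflate_ratio(self):
        universe = [f"G{i}" for i in range(10)]
        bound = GeneSet.from_iterable("bound", ["G1", "G1", "G1"])
        table = regulatory.binding_ratio_per_cluster(
            {"c": universe[:4]}, bound, universe
        )
        assert table["n_bound"].iloc[0] == 1

    def test_planted_ordering_recovered(self, rng):
        # clusters 1-2 planted 70% bound, clusters 3-4 planted 20%
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            universe = [f"G{i}" for i in range(400)]
            clusters, bound = {}, set()
            for c in range(4):
                members = universe[c * 50 : (c + 1) * 50]
                clusters[f"c{c + 1}"] = members
                frac = 0.7 if c < 2 else 0.2
                bound |= set(
                    r.choice(members, int(frac * 50), replace=False)
                )
            table = regulatory.binding_ratio_per_cluster(
                clusters, GeneSet.from_iterable("b", bound), universe
            ).set_index("cluster")
            hits += (
                min(table.loc["c1", "ratio"], table.loc["c2", "ratio"])
                > max(table.loc["c3", "ratio"], table.loc["c4", "ratio"])
            )
        assert hits >= 19


class TestTfAnalyses:
    def test_phagocyte_specific_tf_retained(self):
        scores = pd.DataFrame(
            {
                "Monocyte": [2.0, 0.5], "DC": [1.8, 0.5],
                "B": [0.0, 0.5], "CD4T": [0.1, 0.5],
            },
            index=["SPECIFIC", "UBIQUITOUS"],
        )
        keep = regulatory.tf_specificity_filter(scores, ["Monocyte", "DC"], 2.0)
        assert keep == ["SPECIFIC"]

    def test_exact_boundary_rejected(self):
        # after shifting by the global minimum (0) plus 0.1, the phagocyte
        # minimum is exactly fold_cut times the other maximum -> rejected
        scores = pd.DataFrame(
            {"Monocyte": [0.3], "B": [0.1], "NK": [0.0]}, index=["EDGE"]
        )
        assert regulatory.tf_specificity_filter(scores, ["Monocyte"], 2.0) == []

    def test_enrichment_matches_enumeration(self):
        import itertools
        import math

        universe = [f"G{i}" for i in range(10)]
        query = GeneSet.from_iterable("q", universe[:4])
        targets = universe[:5]
        table = regulatory.tf_target_enrichment(
            {"TF1": targets}, query, universe
        )
        observed = table["overlap"].iloc[0]
        draws = list(itertools.combinations(universe, len(targets)))
        expected = sum(
            1 for d in draws if len(set(d) & query.members) >= observed
        ) / len(draws)
        assert table["p"].iloc[0] == pytest.approx(expected)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            regulatory.tf_target_enrichment(
                {"TF1": ["G1"]}, GeneSet.from_iterable("q", []), ["G1", "G2"]
            )
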