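"""Decade-bin profiles, slope statistic, pattern selection, LHA subtraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from conftest import expression_from_values
from lhasig import age_patterns, preprocess, simulate
from lhasig.age_patterns import PatternGroup
from lhasig.containers import GeneSet
from lhasig.simulate import DECADE_BINS, AgeSeriesConfig


def _age_meta(n_per_bin):
    ages = np.repeat(np.arange(20, 80, 10), n_per_bin) + 3
    return pd.DataFrame({"group": "pop", "age": ages})


class TestBinProfiles:
    def test_constant_gene_scores_zero(self):
        meta = _age_meta(2)
        em = expression_from_values(np.full((3, 12), 7.0), meta)
        prof = age_patterns.bin_profiles(em)
        np.testing.assert_allclose(prof.values, 0.0)

    def test_age_tracking_gene_increases(self):
        meta = _age_meta(2)
        em = expression_from_values(
            np.tile(meta["age"].values[None, :].astype(float), (2, 1)), meta
        )
        prof = age_patterns.bin_profiles(em)
        assert (np.diff(prof.iloc[0]) > 0).all()

    def test_affine_invariance(self, rng):
        meta = _age_meta(3)
        values = rng.normal(0, 1, (5, 18))
        a = age_patterns.bin_profiles(expression_from_values(values, meta))
        b = age_patterns.bin_profiles(
            expression_from_values(3.5 * values - 2.0, meta)
        )
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestSlopeValue:
    @pytest.mark.parametrize(
        "last_three, expected",
        [
            ((1.0, 2.0, 3.0), 1.0),
            ((1.0, 2.0, 1.0), -1.0),
            # reference near-flat case: positive slope yet a final-decade
            # gap of only 0.03944, handled by the flatness rule
            ((0.0, -0.16494, -0.20438), (-0.16494) * (-0.20438 + 0.16494)),
        ],
    )
    def test_slope_examples(self, last_three, expected):
        centroid = [0.0, 0.0, 0.0, *last_three]
        assert age_patterns.slope_value(centroid) == pytest.approx(expected)

    def test_translation_invariance_and_quadratic_scaling(self, rng):
        for _ in range(20):
            m = rng.normal(0, 1, 6)
            base = age_patterns.slope_value(m)
            assert age_patterns.slope_value(m + 3.3) == pytest.approx(base)
            assert age_patterns.slope_value(2.0 * m) == pytest.approx(4.0 * base)

    def test_positive_for_monotone_tail(self, rng):
        for _ in range(20):
            tail = np.sort(rng.normal(0, 1, 3))
            if len(set(tail)) < 3:
                continue
            m = np.concatenate([rng.normal(0, 1, 3), tail])
            assert age_patterns.slope_value(m) > 0


class TestClusterPatterns:
    def test_duplicated_archetypes_separate_perfectly(self):
        up = simulate.archetype_profile("monotone_up")
        down = simulate.archetype_profile("monotone_down")
        profiles = pd.DataFrame(
            np.vstack([np.tile(up, (10, 1)), np.tile(down, (10, 1))]),
            index=simulate.gene_ids(20), columns=DECADE_BINS,
        )
        groups = age_patterns.cluster_patterns(profiles)
        assert len(groups) == 2
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [10, 10]

    def test_archetype_recovery_under_noise(self):
        # four archetypes, 30 genes each, noise sd 0.3 on the count scale:
        # clustering of the planted genes' bin profiles recovers the
        # archetype partition with ARI >= 0.9 averaged over 10 seeds
        aris = []
        for seed in range(10):
            cfg = AgeSeriesConfig(
                seed=seed, n_genes=120, n_per_bin=20, noise_sd=0.3,
                archetypes={
                    "monotone_up": range(0, 30),
                    "monotone_down": range(30, 60),
                    "rise_fall": range(60, 90),
                    "late_spike": range(90, 120),
                },
            )
            cm, truth = simulate.simulate_age_series(cfg)
            em = preprocess.log_normalize(cm)
            profiles = age_patterns.bin_profiles(em)
            groups = age_patterns.cluster_patterns(profiles)
            labels = pd.Series(0, index=profiles.index)
            for g in groups:
                labels[g.members] = g.group_id
            aris.append(
                adjusted_rand_score(truth["archetype"].values, labels.values)
            )
        assert np.mean(aris) >= 0.9

    def test_deterministic_given_input(self, rng):
        profiles = pd.DataFrame(
            rng.normal(0, 1, (30, 6)), index=simulate.gene_ids(30),
            columns=DECADE_BINS,
        )
        a = age_patterns.cluster_patterns(profiles)
        b = age_patterns.cluster_patterns(profiles.sample(frac=1, random_state=0))
        assert [g.members for g in a] == [g.members for g in b]


class TestSelection:
    def _group(self, centroid, n=5, gid=1):
        centroid = np.asarray(centroid, dtype=float)
        return PatternGroup(
            group_id=gid, members=[f"G{gid}_{i}" for i in range(n)],
            centroid=centroid, slope_value=age_patterns.slope_value(centroid),
        )

    def test_monotone_up_selected_as_up(self):
        g = self._group(simulate.archetype_profile("monotone_up"))
        up, down = age_patterns.select_age_groups([g])
        assert g.selected and g.direction == "up"
        assert set(g.members) == up.members and len(down) == 0

    def test_rise_then_fall_rejected(self):
        g = self._group(simulate.archetype_profile("rise_fall"))
        age_patterns.select_age_groups([g])
        assert not g.selected and g.reason == "non_monotone"

    def test_flat_final_gap_rejected_despite_positive_slope(self):
        # final bin means -0.16494 (60-69) and -0.20438 (70-79):
        # |gap| = 0.03944 < 0.05 so the group is rejected as flat
        g = self._group([0.3, 0.2, 0.1, 0.0, -0.16494, -0.20438])
        assert g.slope_value > 0
        age_patterns.select_age_groups([g])
        assert not g.selected and g.reason == "flat"

    def test_two_gene_group_never_selected(self):
        g = self._group(simulate.archetype_profile("monotone_up"), n=2)
        up, _ = age_patterns.select_age_groups([g])
        assert not g.selected and g.reason == "too_small" and len(up) == 0

    def test_late_spike_selected_via_spike_rule(self):
        g = self._group([0.0, 0.0, 0.0, 0.0, 0.0, 0.8])
        assert g.slope_value == 0.0
        up, _ = age_patterns.select_age_groups([g], spike_delta=0.5)
        assert g.selected and g.reason == "late_spike"
        assert set(g.members) == up.members


class TestAgeAssociation:
    def test_null_pvalues_uniform(self):
        cfg = AgeSeriesConfig(seed=31, n_genes=1000, n_per_bin=15)
        cm, _ = simulate.simulate_age_series(cfg)
        em = preprocess.log_normalize(cm)
        assoc = age_patterns.age_association_test(em, covariates=["sex"])
        assert stats.kstest(assoc["p"], "uniform").pvalue > 0.01

    def test_power_on_planted_monotone_genes(self):
        # amplitude-1 monotone genes at noise sd 0.5, 20 samples per bin:
        # nearly all planted genes reach padj < 0.05
        rates = []
        for seed in range(5):
            cfg = AgeSeriesConfig(
                seed=seed, n_genes=500, n_per_bin=20, noise_sd=0.5,
                archetypes={"monotone_up": range(50)},
            )
            cm, _ = simulate.simulate_age_series(cfg)
            em = preprocess.log_normalize(cm)
            assoc = age_patterns.age_association_test(em, covariates=["sex"])
            rates.append((assoc["padj"].iloc[:50] < 0.05).mean())
        assert np.mean(rates) >= 0.95

    def test_empty_bin_rejected(self):
        meta = pd.DataFrame({"age": [25, 25, 35, 35]})
        em = expression_from_values(np.random.default_rng(0).normal(size=(3, 4)), meta)
        with pytest.raises(ValueError):
            age_patterns.age_association_test(em, ages=em.metadata["age"])


class TestDeriveLha:
    def test_no_aging_sets_is_identity(self):
        up = GeneSet.from_iterable("u", "ABC", "up")
        down = GeneSet.from_iterable("d", "XY", "down")
        result = age_patterns.derive_lha(up, down, [])
        assert result.lha_up.members == up.members
        assert result.lha_down.members == down.members

    def test_complete_overlap_empties_lha(self):
        up = GeneSet.from_iterable("u", "ABC", "up")
        aging = GeneSet.from_iterable("aging", "ABCDEF")
        result = age_patterns.derive_lha(
            up, GeneSet.from_iterable("d", "", "down"), [aging]
        )
        assert len(result.lha_up) == 0
        assert result.provenance["A"] == ["aging"]

    def test_external_set_contributes_to_removal(self):
        up = GeneSet.from_iterable("u", "ABCD", "up")
        aging = GeneSet.from_iterable("aging", "A")
        external = GeneSet.from_iterable("meta_analysis", "B")
        result = age_patterns.derive_lha(
            up, GeneSet.from_iterable("d", "", "down"), [aging], external
        )
        assert result.lha_up.members == {"C", "D"}
        assert result.provenance == {"A": ["aging"], "B": ["meta_analysis"]}
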