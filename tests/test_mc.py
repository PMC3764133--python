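import itertools

import numpy as np
import pytest

import varldkit as vk
from varldkit.exceptions import PanelError

from conftest import panel_from_dosages


class TestMergePanels:
    def test_sample_counts_add(self, null_pair):
        p1, p2 = null_pair
        h1, h2 = vk.harmonize_panels(p1, p2)
        merged = vk.merge_panels(h1, h2.subset_samples(range(40)))
        assert merged.n_samples == h1.n_samples + 40

    def test_merged_frequency_is_weighted_mean(self):
        p1 = panel_from_dosages([[0], [1], [2]])           # freq 0.5, n=3
        p2 = panel_from_dosages([[2], [2]], population="q")  # freq 1.0, n=2
        merged = vk.merge_panels(p1, p2)
        f = vk.allele_frequency(merged, "rs1")
        assert f == pytest.approx((0.5 * 6 + 1.0 * 4) / 10)

    def test_self_merge_duplicates_columns(self, null_pair):
        p1, _ = null_pair
        merged = vk.merge_panels(p1, p1)
        np.testing.assert_allclose(merged.dosages[:p1.n_samples],
                                   merged.dosages[p1.n_samples:])

    def test_variant_mismatch_rejected(self):
        p1 = panel_from_dosages([[0], [1], [2]], positions=[100])
        p2 = panel_from_dosages([[0], [1], [2]], positions=[200])
        with pytest.raises(PanelError):
            vk.merge_panels(p1, p2)


class TestResampleSplit:
    def test_partition_covers_merged_sample_set(self, null_pair, rng):
        p1, p2 = null_pair
        merged = vk.merge_panels(*vk.harmonize_panels(p1, p2))
        q1, q2 = vk.resample_split(merged, 70, 50, rng)
        assert (q1.n_samples, q2.n_samples) == (70, 50)
        pooled = np.vstack([q1.dosages, q2.dosages])
        # same multiset of rows as the merged panel
        assert sorted(map(tuple, pooled)) == sorted(map(tuple, merged.dosages))

    def test_size_mismatch_rejected(self, null_pair, rng):
        p1, p2 = null_pair
        merged = vk.merge_panels(*vk.harmonize_panels(p1, p2))
        with pytest.raises(ValueError):
            vk.resample_split(merged, 10, 10, rng)

    def test_partitions_uniform_over_10000_draws(self, rng):
        # 4 individuals with distinct dosage signatures, split 2/2:
        # each of the 6 unordered first-group pairs should appear ~1/6
        dos = np.array([[0, 0], [1, 0], [2, 0], [0, 1]], float)
        merged = panel_from_dosages(dos)
        counts = {frozenset(pair): 0
                  for pair in itertools.combinations(range(4), 2)}
        sig = {tuple(dos[i]): i for i in range(4)}
        n_draws = 10_000
        for _ in range(n_draws):
            q1, _ = vk.resample_split(merged, 2, 2, rng)
            got = frozenset(sig[tuple(row)] for row in q1.dosages)
            counts[got] += 1
        p = 1 / 6
        sigma = np.sqrt(n_draws * p * (1 - p))
        for c in counts.values():
            assert abs(c - n_draws * p) < 3 * sigma


class TestMCPvalue:
    def test_identical_panels_give_p_one(self, null_pair):
        p1, _ = null_pair
        res = vk.mc_pvalue(p1, p1, b=99, rng_seed=5)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_determinism_same_seed(self, null_pair):
        p1, p2 = null_pair
        h1, h2 = vk.harmonize_panels(p1, p2)
        a = vk.mc_pvalue(h1, h2, b=150, rng_seed=42)
        c = vk.mc_pvalue(h1, h2, b=150, rng_seed=42)
        np.testing.assert_array_equal(a.replicates, c.replicates)
        assert a.p_value == c.p_value
        d = vk.mc_pvalue(h1, h2, b=150, rng_seed=43)
        assert not np.array_equal(a.replicates, d.replicates)

    def test_fast_and_panel_paths_agree(self, null_pair):
        # the missing-data slow path and the vectorised path implement the
        # same permutation scheme; with the same seed they must agree
        p1, p2 = null_pair
        h1, h2 = vk.harmonize_panels(p1, p2)
        fast = vk.mc_pvalue(h1, h2, b=25, mode="genotype_corr", rng_seed=9)
        # force the panel-based path by inserting one missing dosage entry
        d1 = h1.dosages.copy()
        d1[0, 0] = np.nan
        g1 = vk.GenotypePanel(h1.population, list(h1.variants), d1)
        slow = vk.mc_pvalue(g1, vk.GenotypePanel(h2.population,
                                                 list(h2.variants),
                                                 h2.dosages.copy()),
                            b=25, mode="genotype_corr", rng_seed=9)
        # one masked entry out of ~1800: replicate scores nearly identical
        assert np.max(np.abs(fast.replicates - slow.replicates)) < 0.5

    def test_invalid_b_rejected(self, null_pair):
        p1, _ = null_pair
        with pytest.raises(ValueError):
            vk.mc_pvalue(p1, p1, b=0)

    def test_unharmonized_panels_rejected(self, null_pair):
        p1, p2 = null_pair
        with pytest.raises(PanelError):
            vk.mc_pvalue(p1.subset_variants(range(5)), p2, b=10)

    def test_floor_is_one_over_b_plus_one(self, divergent_pair):
        p1, p2 = divergent_pair
        h1, h2 = vk.harmonize_panels(p1, p2)
        res = vk.mc_pvalue(h1, h2, b=199, rng_seed=0)
        assert res.p_value >= 1 / 200


class TestBonferroni:
    def test_ten_comparisons_at_family_alpha_005(self):
        alpha_per_test, flags = vk.bonferroni_adjust(
            [0.0001] * 5 + [0.0245, 0.1264, 0.2744, 0.0195, 0.0001], 0.05)
        assert alpha_per_test == pytest.approx(0.005)
        assert flags.tolist() == [True] * 5 + [False, False, False, False, True]

    def test_single_test_threshold_is_family_alpha(self):
        alpha_per_test, flags = vk.bonferroni_adjust([0.01], 0.05)
        assert alpha_per_test == 0.05
        assert flags.tolist() == [True]

    def test_p_equal_to_threshold_not_significant(self):
        _, flags = vk.bonferroni_adjust([0.025, 0.0249], 0.05)
        assert flags.tolist() == [False, True]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vk.bonferroni_adjust([], 0.05)


class TestPairwiseComparisonTable:
    def test_self_pair_p_one_not_significant(self, null_pair):
        p1, _ = null_pair
        tab = vk.pairwise_comparison_table(
            {"X": p1}, [("X", "X")], b=49, rng_seed=1)
        row = tab.rows.iloc[0]
        assert row.p_value == 1.0
        assert not row.significant

    def test_only_divergent_pairs_flagged(self):
        # three populations: A and B from one law, C LD-divergent
        cfg_null = vk.SimulationConfig(m=20, n1=80, n2=80,
                                       structure=vk.ar1(0.9), seed=21)
        pa, pb = vk.simulate_pair(cfg_null)
        cfg_alt = vk.SimulationConfig(m=20, n1=80, n2=80,
                                      structure=vk.ar1(0.9),
                                      divergence=("ar1_contrast", 0.9, 0.2),
                                      seed=21)
        _, pc = vk.simulate_pair(cfg_alt)
        panels = {"A": pa, "B": pb, "C": pc}
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        tab = vk.pairwise_comparison_table(panels, pairs, b=999, rng_seed=4)
        flags = dict(zip([f"{a}-{b}" for a, b in pairs],
                         tab.rows.significant))
        assert not flags["A-B"]
        assert flags["A-C"] and flags["B-C"]
        assert tab.alpha_per_test == pytest.approx(0.05 / 3)

    def test_unknown_label_rejected(self, null_pair):
        p1, _ = null_pair
        with pytest.raises(KeyError):
            vk.pairwise_comparison_table({"X": p1}, [("X", "Y")], b=9)

    def test_pooled_panel_concatenates_members(self, null_pair):
        p1, p2 = null_pair
        p2 = vk.GenotypePanel("P2", list(p2.variants), p2.dosages,
                              haplotypes=p2.haplotypes, phased=True)
        tab = vk.pairwise_comparison_table(
            {"P1": p1, "P2": p2}, [("P1", "POOL")], b=49, rng_seed=2,
            pools={"POOL": ["P1", "P2"]})
        assert tab.rows.iloc[0].m_snps > 0
        assert tab.n_comparisons == 1

    def test_rows_reproducible_independently(self, null_pair):
        p1, p2 = null_pair
        p2 = vk.GenotypePanel("P2", list(p2.variants), p2.dosages,
                              haplotypes=p2.haplotypes, phased=True)
        panels = {"P1": p1, "P2": p2}
        both = vk.pairwise_comparison_table(
            panels, [("P1", "P2"), ("P2", "P1")], b=59, rng_seed=77)
        first = vk.pairwise_comparison_table(
            panels, [("P1", "P2")], b=59, rng_seed=77)
        assert both.rows.iloc[0].p_value == first.rows.iloc[0].p_value
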