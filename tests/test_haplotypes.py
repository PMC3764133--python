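import numpy as np
import pytest

import varldkit as vk
from varldkit.exceptions import UndefinedLDError

from conftest import panel_from_dosages, panel_from_haplotypes


def sample_from_freq_table(rng, freqs, n_ind):
    """Draw 2*n_ind haplotypes from an explicit frequency table and pair
    them into unphased individuals; returns (panel, empirical_freqs)."""
    k = len(next(iter(freqs)))
    haps = list(freqs)
    draws = rng.choice(len(haps), size=2 * n_ind, p=list(freqs.values()))
    hap_matrix = np.array([[int(c) for c in haps[d]] for d in draws], float)
    empirical = {h: np.mean(draws == i) for i, h in enumerate(haps)}
    dosages = hap_matrix[0::2] + hap_matrix[1::2]
    return panel_from_dosages(dosages), empirical


class TestEMHaplotypeFreqs:
    def test_phased_panel_equals_direct_counting(self, rng):
        haps = (rng.random((60, 4)) < 0.5).astype(float)
        panel = panel_from_haplotypes(haps)
        tab = vk.em_haplotype_freqs(panel, panel.variant_ids)
        strings = ["".join(str(int(x)) for x in row) for row in haps]
        for h, f in tab.as_dict().items():
            assert f == pytest.approx(strings.count(h) / len(strings))
        assert tab.n_chromosomes == 60
        assert tab.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_perfectly_correlated_snps_resolve_to_two_haplotypes(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2], [1, 1]], float)
        tab = vk.em_haplotype_freqs(panel_from_dosages(g), ["rs1", "rs2"])
        d = tab.as_dict()
        assert d.get("01", 0.0) < 1e-6 and d.get("10", 0.0) < 1e-6
        assert d["00"] + d["11"] == pytest.approx(1.0, abs=1e-6)

    def test_recovers_generating_frequencies(self, rng):
        freqs = {"000": 0.4, "111": 0.3, "100": 0.2, "011": 0.1}
        panel, empirical = sample_from_freq_table(rng, freqs, n_ind=150)
        tab = vk.em_haplotype_freqs(panel, panel.variant_ids)
        est = tab.as_dict()
        for h, f in empirical.items():
            assert est.get(h, 0.0) == pytest.approx(f, abs=0.02)

    def test_log_likelihood_non_decreasing_in_iterations(self, rng):
        freqs = {"00": 0.35, "11": 0.35, "10": 0.2, "01": 0.1}
        panel, _ = sample_from_freq_table(rng, freqs, n_ind=40)
        lls = [vk.em_haplotype_freqs(panel, panel.variant_ids,
                                     max_iter=i, tol=0.0).log_likelihood
               for i in range(1, 9)]
        assert np.all(np.diff(lls) >= -1e-10)

    def test_k_out_of_range_rejected(self, null_pair):
        p1, _ = null_pair
        with pytest.raises(ValueError):
            vk.em_haplotype_freqs(p1, p1.variant_ids[:1])
        with pytest.raises(ValueError):
            vk.em_haplotype_freqs(p1, p1.variant_ids[:13])

    def test_all_missing_rows_dropped(self):
        g = np.array([[0, 1], [np.nan, np.nan], [2, 1], [1, 0]], float)
        tab = vk.em_haplotype_freqs(panel_from_dosages(g), ["rs1", "rs2"])
        assert tab.n_chromosomes == 6

    def test_common_view_applies_5pct_threshold(self, rng):
        freqs = {"00": 0.55, "11": 0.41, "10": 0.04}
        panel, empirical = sample_from_freq_table(rng, freqs, n_ind=400)
        tab = vk.em_haplotype_freqs(panel, panel.variant_ids)
        common = tab.common(min_freq=0.05)
        assert set(common.haplotypes) == {"00", "11"}


class TestEMTwoLocus:
    def test_unambiguous_data_exact(self):
        # dosage pairs with no double heterozygote
        g1 = np.array([2, 2, 0, 0, 1, 1], float)
        g2 = np.array([2, 2, 0, 0, 0, 2], float)
        p_ab, p_a, p_b = vk.em_two_locus(g1, g2)
        # haplotypes: 4x(1,1), 4x(0,0), (1,0)+(0,0), (1,1)+(0,1)
        assert p_a == pytest.approx(6 / 12)
        assert p_b == pytest.approx(6 / 12)
        assert p_ab == pytest.approx(5 / 12)

    def test_matches_phased_counting_at_large_n(self):
        cfg = vk.SimulationConfig(m=2, n1=800, n2=10,
                                  structure=vk.ar1(0.6), seed=3)
        panel, _ = vk.simulate_pair(cfg)
        h = panel.haplotypes
        p_ab_true = np.mean(h[:, 0] * h[:, 1])
        p_ab, _, _ = vk.em_two_locus(panel.dosages[:, 0], panel.dosages[:, 1])
        assert p_ab == pytest.approx(p_ab_true, abs=0.02)


class TestDprimeCI:
    def test_perfect_ld_high_lower_bound(self, rng):
        hap = (rng.random(200) < 0.4).astype(float)
        haps = np.column_stack([hap, hap])
        panel = panel_from_haplotypes(haps)
        unphased = panel_from_dosages(panel.dosages)
        lo, hi = vk.dprime_ci(unphased, "rs1", "rs2")
        assert lo > 0.9
        assert hi == pytest.approx(1.0)

    def test_independent_snps_upper_bound_mostly_low(self, rng):
        n_low = 0
        runs = 20
        for _ in range(runs):
            g1 = rng.binomial(2, 0.5, size=100).astype(float)
            g2 = rng.binomial(2, 0.5, size=100).astype(float)
            try:
                _, hi = vk.dprime_ci(panel_from_dosages(
                    np.column_stack([g1, g2])), "rs1", "rs2")
            except UndefinedLDError:
                continue
            n_low += hi < 0.9
        assert n_low >= 0.75 * runs

    def test_interval_within_unit_box(self, null_pair):
        p1, _ = null_pair
        ids = p1.variant_ids
        for i, j in [(0, 1), (0, 5), (3, 9)]:
            lo, hi = vk.dprime_ci(p1, ids[i], ids[j])
            assert 0.0 <= lo <= hi <= 1.0


def perfect_cluster_haps(rng, n_hap, k, freq=0.4):
    base = (rng.random(n_hap) < freq).astype(float)
    return np.tile(base[:, None], (1, k))


class TestFindBlocks:
    def test_all_perfect_ld_single_block(self, rng):
        haps = perfect_cluster_haps(rng, 120, 5)
        panel = panel_from_haplotypes(haps)
        blocks = vk.find_blocks(panel, method="gabriel")
        assert len(blocks) == 1
        assert blocks[0].snp_ids == panel.variant_ids
        assert blocks[0].start_bp == panel.variants[0].pos
        assert blocks[0].end_bp == panel.variants[-1].pos

    @pytest.mark.parametrize("method", ["gabriel", "four_gamete"])
    def test_two_clusters_split_by_unlinked_snp(self, rng, method):
        c1 = perfect_cluster_haps(rng, 160, 3, freq=0.4)
        mid = (rng.random(160) < 0.5).astype(float)[:, None]
        c2 = perfect_cluster_haps(rng, 160, 3, freq=0.3)
        panel = panel_from_haplotypes(np.hstack([c1, mid, c2]))
        blocks = vk.find_blocks(panel, method=method)
        member_sets = [b.snp_ids for b in blocks]
        assert panel.variant_ids[:3] in member_sets
        assert panel.variant_ids[4:] in member_sets
        assert all(panel.variant_ids[3] not in s for s in member_sets)

    def test_blocks_disjoint_and_sorted(self, divergent_pair):
        p1, _ = divergent_pair
        blocks = vk.find_blocks(p1, method="four_gamete")
        seen = []
        for b in blocks:
            assert b.n_snps >= 2
            assert not (set(b.snp_ids) & set(seen))
            seen.extend(b.snp_ids)
        starts = [b.start_bp for b in blocks]
        assert starts == sorted(starts)

    def test_unknown_method_rejected(self, null_pair):
        with pytest.raises(ValueError):
            vk.find_blocks(null_pair[0], method="nope")

    def test_bed_export_is_zero_based_half_open(self, rng, tmp_path):
        haps = perfect_cluster_haps(rng, 100, 3)
        panel = panel_from_haplotypes(haps)
        blocks = vk.find_blocks(panel, method="four_gamete")
        out = tmp_path / "blocks.bed"
        from varldkit.haplotypes import write_blocks_bed
        write_blocks_bed(blocks, str(out))
        line = out.read_text().strip().split("\t")
        assert int(line[1]) == blocks[0].start_bp - 1
        assert int(line[2]) == blocks[0].end_bp


class TestSelectTags:
    def test_single_tag_when_all_r2_one(self):
        mat = vk.LDMatrix(["a", "b", "c"], np.ones((3, 3)), "x")
        ts = vk.select_tags(mat, 0.8)
        assert ts.tags == ["a"]
        assert set(ts.coverage_map) == {"b", "c"}

    def test_every_snp_own_tag_when_independent(self):
        mat = vk.LDMatrix(["a", "b", "c"], np.eye(3), "x")
        ts = vk.select_tags(mat, 0.8)
        assert sorted(ts.tags) == ["a", "b", "c"]
        assert ts.coverage_map == {}

    def test_two_clusters_two_tags(self):
        r = np.eye(6)
        r[np.ix_([0, 1, 2], [0, 1, 2])] = 1.0
        r[np.ix_([3, 4, 5], [3, 4, 5])] = 1.0
        mat = vk.LDMatrix(list("abcdef"), r, "x")
        ts = vk.select_tags(mat, 0.8)
        assert len(ts.tags) == 2

    def test_coverage_postcondition(self, divergent_pair):
        p1, _ = divergent_pair
        mat = vk.ld_matrix(p1)
        ts = vk.select_tags(mat, r2_threshold=0.5)
        for snp, (tag, r2) in ts.coverage_map.items():
            assert r2 >= 0.5
            assert tag in ts.tags
        assert set(ts.tags) | set(ts.coverage_map) == set(mat.variant_ids)
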