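"""SNP-map comparison: category partition, density, order concordance."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvrkit.mapdiff import (
    CATEGORIES,
    classify_marker_pairs,
    position_concordance,
    snp_density,
)
from cnvrkit.simulate import simulate_map_pair
from cnvrkit.types import GenomeBuild, SnpMarker

from conftest import small_sim_config
from oracles import discordant_pairs_bruteforce


def m(name, chrom=None, pos=None):
    return SnpMarker(name, chrom, pos)


class TestClassification:
    def test_each_category_reachable(self):
        a = [m("same", "5", 100), m("diff", "1", 50), m("unkA"),
             m("unkB", "2", 10), m("both"), m("onlyA", "3", 7)]
        b = [m("same", "5", 999), m("diff", "2", 50), m("unkA", "4", 5),
             m("unkB"), m("both"), m("onlyB", "3", 8)]
        comp = classify_marker_pairs(a, b)
        assert comp.counts == {
            "same_chromosome": 1,
            "different_chromosomes": 1,
            "unknown_in_a": 1,
            "unknown_in_b": 1,
            "both_unknown": 1,
            "missing_from_a": 1,
            "missing_from_b": 1,
        }

    def test_same_chromosome_does_not_require_equal_positions(self):
        comp = classify_marker_pairs([m("x", "1", 100)], [m("x", "1", 999_999)])
        assert comp.counts["same_chromosome"] == 1

    def test_self_comparison_only_same_or_both_unknown(self):
        a = [m("a", "1", 1), m("b", "2", 5), m("c")]
        comp = classify_marker_pairs(a, a)
        assert comp.counts["same_chromosome"] == 2
        assert comp.counts["both_unknown"] == 1
        assert sum(comp.counts.values()) == 3

    def test_swap_symmetry(self):
        cfg = small_sim_config(seed=31)
        map_a, map_b, _, _ = simulate_map_pair(cfg)
        fwd = classify_marker_pairs(map_a, map_b)
        rev = classify_marker_pairs(map_b, map_a)
        assert fwd.counts["unknown_in_a"] == rev.counts["unknown_in_b"]
        assert fwd.counts["missing_from_a"] == rev.counts["missing_from_b"]
        assert fwd.counts["same_chromosome"] == rev.counts["same_chromosome"]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_partition_property(self, data):
        names = data.draw(st.sets(st.text(
            alphabet="abcdef", min_size=1, max_size=4), min_size=1, max_size=30))
        def rand_map(tag):
            out = []
            for n in names:
                kind = data.draw(st.integers(0, 3))
                if kind == 0:
                    continue  # missing from this map
                if kind == 1:
                    out.append(m(n))
                else:
                    out.append(m(n, str(kind), data.draw(st.integers(1, 100))))
            return out
        a, b = rand_map("a"), rand_map("b")
        if not a and not b:
            return
        comp = classify_marker_pairs(a, b)
        union = {x.name for x in a} | {x.name for x in b}
        assert sum(comp.counts.values()) == len(union)
        assert set(comp.by_marker) == union

    def test_planted_category_counts_recovered_exactly(self):
        cfg = small_sim_config(seed=33)
        map_a, map_b, truth_cats, _ = simulate_map_pair(cfg)
        comp = classify_marker_pairs(map_a, map_b)
        planted = {c: 0 for c in CATEGORIES}
        for cat in truth_cats.values():
            planted[cat] += 1
        assert comp.counts == planted
        assert comp.by_marker == truth_cats


class TestDensity:
    def test_markers_per_mb(self):
        genome = GenomeBuild("g", {"1": 10_000_000})
        markers = [m(f"s{i}", "1", i * 20_000) for i in range(1, 501)]
        assert snp_density(markers, genome) == {"1": 50.0}

    def test_empty_chromosome_is_zero_with_warning(self, caplog):
        genome = GenomeBuild("g", {"1": 1_000_000, "2": 1_000_000}, 2)
        with caplog.at_level("WARNING"):
            d = snp_density([m("s1", "1", 5)], genome)
        assert d["2"] == 0.0 and "no mapped markers" in caplog.text

    def test_max_position_proxy_without_genome(self, caplog):
        markers = [m(f"s{i}", "1", i * 1_000_000) for i in range(1, 11)]
        with caplog.at_level("WARNING"):
            d = snp_density(markers)
        assert d["1"] == pytest.approx(1.0)
        assert "proxy" in caplog.text


class TestConcordance:
    def test_identical_maps_have_no_discordance(self):
        a = [m(f"s{i}", "1", i * 100) for i in range(1, 20)]
        rep = position_concordance(a, a)
        assert rep.total_discordant_pairs == 0

    def test_single_swap_is_one_discordant_pair(self):
        a = [m("s1", "1", 100), m("s2", "1", 200), m("s3", "1", 300)]
        b = [m("s1", "1", 100), m("s2", "1", 300), m("s3", "1", 200)]
        rep = position_concordance(a, b)
        assert rep.per_chrom["1"].n_discordant_pairs == 1

    def test_cross_chromosome_markers_reported_separately(self):
        a = [m("s1", "1", 100), m("s2", "1", 200)]
        b = [m("s1", "1", 100), m("s2", "2", 200)]
        rep = position_concordance(a, b)
        assert rep.cross_chromosome == ("s2",)
        assert rep.per_chrom["1"].n_markers == 1

    def test_matches_bruteforce_pair_scan_on_random_permutations(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            n = int(rng.integers(2, 200))
            perm = rng.permutation(n)
            a = [m(f"s{i}", "1", (i + 1) * 10) for i in range(n)]
            b = [m(f"s{i}", "1", int(perm[i] + 1) * 10) for i in range(n)]
            rep = position_concordance(a, b)
            assert rep.per_chrom["1"].n_discordant_pairs == \
                discordant_pairs_bruteforce(list(perm))

    def test_unshuffled_simulated_maps_are_concordant(self):
        from cnvrkit.simulate import MapDiscrepancyRates
        cfg = small_sim_config(
            seed=37,
            map_rates=MapDiscrepancyRates(0, 0, 0, 0, 0, 0, local_shuffle=0.0))
        map_a, map_b, _, shuffled = simulate_map_pair(cfg)
        assert shuffled == ()
        assert map_a == map_b
        assert position_concordance(map_a, map_b).total_discordant_pairs == 0
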