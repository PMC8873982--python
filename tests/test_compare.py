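"""Comparison operations: individual vs population overlap, CNVR length
accounting vs basepair oracle, consensus thresholding and pooling."""
import numpy as np
import pytest

from cnvrkit.cnvr import call_cnvr
from cnvrkit.compare import (
    compare_cnv_individual,
    compare_cnv_population,
    compare_cnvr,
    compare_to_database,
    consensus_cnvrs,
    consensus_threshold,
    flag_known_artifacts,
)
from cnvrkit.simulate import simulate_cohort
from cnvrkit.types import CnvCall, CnvError, CnvRegion

from conftest import random_calls, small_sim_config
from oracles import bp_overlap_length, overlap_counts


def call(start, end, sid="S1", cn=1, chrom="1", caller="penncnv", build=""):
    return CnvCall(sid, chrom, start, end, cn, 3, caller=caller, build=build)


def region(rid, start, end, typ="loss", chrom="1", n=1):
    return CnvRegion(rid, chrom, start, end, typ, n_samples=n, n_calls=n)


class TestCompareCnv:
    def test_individual_same_sample_overlap(self):
        rep = compare_cnv_individual([call(100, 200)], [call(150, 250)])
        assert rep.a.pct_overlapped == 100.0
        assert rep.a.n_same_state == 1

    def test_individual_sample_mismatch_is_zero(self):
        rep = compare_cnv_individual([call(100, 200, "S1")], [call(100, 200, "S2")])
        assert rep.a.n_overlapped == 0

    def test_population_ignores_sample(self):
        rep = compare_cnv_population([call(100, 200, "S1")], [call(100, 200, "S2")])
        assert rep.a.pct_overlapped == rep.b.pct_overlapped == 100.0

    def test_state_breakdown(self):
        rep = compare_cnv_population([call(100, 200, cn=1)], [call(150, 250, cn=3)])
        assert (rep.a.n_same_state, rep.a.n_different_state) == (0, 1)

    def test_swapping_arguments_swaps_directions(self):
        rng = np.random.default_rng(10)
        a, b = random_calls(rng, 30), random_calls(rng, 25)
        fwd = compare_cnv_population(a, b)
        rev = compare_cnv_population(b, a)
        assert fwd.a == rev.b and fwd.b == rev.a

    def test_matches_all_pairs_oracle_and_population_dominates(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = random_calls(rng, int(rng.integers(1, 40)))
            b = random_calls(rng, int(rng.integers(1, 40)))
            ind = compare_cnv_individual(a, b)
            pop = compare_cnv_population(a, b)
            assert ind.a.n_overlapped == overlap_counts(a, b, same_sample=True)
            assert pop.a.n_overlapped == overlap_counts(a, b, same_sample=False)
            assert pop.a.pct_overlapped >= ind.a.pct_overlapped
            assert pop.b.pct_overlapped >= ind.b.pct_overlapped

    def test_empty_lists_warn(self, caplog):
        with caplog.at_level("WARNING"):
            rep = compare_cnv_individual([], [call(1, 10)])
        assert rep.a.n_total == 0 and "empty" in caplog.text


class TestCompareCnvr:
    def test_union_prevents_double_counting(self):
        a = [region("A1", 100, 300)]
        b = [region("B1", 200, 400), region("B2", 250, 350)]
        pairs, rep = compare_cnvr(a, b)
        assert rep.n_a_hit == 1 and rep.n_b_hit == 2
        assert rep.overlap_bp == 101  # union of 200-300 and 250-300

    def test_identical_lists_are_fully_overlapped(self):
        a = [region("A1", 100, 300), region("A2", 500, 900, chrom="2")]
        _, rep = compare_cnvr(a, a)
        assert rep.pct_len_a == rep.pct_len_b == 100.0
        assert rep.pct_a_hit == rep.pct_b_hit == 100.0

    def test_matches_bp_oracle_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = call_cnvr(random_calls(rng, int(rng.integers(1, 40))), id_prefix="A")
            b = call_cnvr(random_calls(rng, int(rng.integers(1, 40))), id_prefix="B")
            _, rep = compare_cnvr(a, b)
            assert rep.overlap_bp == bp_overlap_length(a, b, 100_000)
            assert rep.overlap_bp <= min(rep.total_len_a, rep.total_len_b)

    def test_pair_fractions_are_consistent(self):
        pairs, _ = compare_cnvr([region("A1", 100, 199)], [region("B1", 150, 349)])
        (p,) = pairs
        assert p.overlap_bp == 50
        assert p.frac_a == pytest.approx(0.5)
        assert p.frac_b == pytest.approx(0.25)


class TestConsensusThreshold:
    @pytest.mark.parametrize("sizes,p,expected", [
        ([403, 397, 393], 0.05, 20),  # ceil(19.65)
        ([400], 0.05, 20),            # exact product must not round up to 21
        ([100], 0.05, 5),
        ([393], 0.10, 40),
    ])
    def test_ceiling_of_min_times_proportion(self, sizes, p, expected):
        assert consensus_threshold(sizes, p) == expected

    def test_empty_rejected(self):
        with pytest.raises(CnvError):
            consensus_threshold([])


class TestConsensusCnvrs:
    def test_distinct_samples_counted_once_across_callers(self):
        a = [call(100, 200, f"S{i}", caller="penncnv") for i in range(10)]
        b = [call(120, 220, f"S{i}", caller="cnvpartition") for i in range(10)]
        cs = consensus_cnvrs([a, b], threshold_n=10)
        assert len(cs.regions) == 1
        assert cs.regions[0].n_samples == 10

    def test_below_threshold_excluded(self):
        a = [call(100, 200, f"S{i}") for i in range(19)]
        cs = consensus_cnvrs([a], threshold_n=20)
        assert cs.regions == ()
        assert len(cs.union_regions) == 1

    def test_single_list_threshold_one_reproduces_call_cnvr(self):
        rng = np.random.default_rng(13)
        calls = random_calls(rng, 50)
        cs = consensus_cnvrs([calls], threshold_n=1)
        assert list(cs.regions) == call_cnvr(calls, source="union")

    def test_build_mismatch_rejected(self):
        with pytest.raises(CnvError):
            consensus_cnvrs([[call(1, 10, build="A")], [call(1, 10, build="B")]], 1)

    def test_planted_frequencies_recovered_at_5pct(self):
        # archetypes at 2%, 5% and 30%: exactly those whose realized carrier
        # count reaches the threshold come through the consensus set
        cfg = small_sim_config(seed=21, fp_call_rate=0.0, qc_fail_frac=0.0,
                               breakpoint_jitter_frac=0.0)
        bundle = simulate_cohort(cfg)
        thr = consensus_threshold([cfg.n_samples], 0.05)
        cs = consensus_cnvrs([bundle.penncnv_calls, bundle.cnvpartition_calls], thr)
        expected = {(p.chrom, p.start, p.end) for p in bundle.truth.planted
                    if p.n_carriers >= thr}
        got = {(r.chrom, r.start, r.end) for r in cs.regions}
        assert got == expected


class TestDatabaseCompare:
    def test_study_fully_inside_external(self):
        study = [region("A1", 100, 200)]
        rep = compare_to_database(study, [region("DB1", 1, 1000)])
        assert rep.pct_study_hit == 100.0 and rep.pct_study_len == 100.0

    def test_disjoint_means_population_specific(self):
        study = [region("A1", 100, 200), region("A2", 500, 600)]
        rep = compare_to_database(study, [region("DB1", 10_000, 20_000)])
        assert rep.n_study_hit == 0 and rep.n_study_specific == 2

    def test_counts_match_bp_oracle(self):
        rng = np.random.default_rng(14)
        study = call_cnvr(random_calls(rng, 30), id_prefix="S")
        ext = call_cnvr(random_calls(rng, 30), id_prefix="D")
        rep = compare_to_database(study, ext)
        assert rep.overlap_bp == bp_overlap_length(study, ext, 100_000)


class TestBlacklist:
    def test_flagging_boundaries(self):
        bl = [("1", 1000, 2000, "FP_1")]
        inside = region("A1", 1500, 1600)
        past = region("A2", 2001, 2500)
        flagged = flag_known_artifacts([inside, past], bl)
        assert [(r.region_id, b) for r, b in flagged] == [("A1", "FP_1")]

    def test_planted_blacklist_hits_exactly_recovered(self):
        rng = np.random.default_rng(15)
        regions = [region(f"R{i}", 10_000 * i + 1, 10_000 * i + 500, chrom="1")
                   for i in range(1, 11)]
        bl = [("1", regions[i].start, regions[i].end, f"FP_{i}") for i in (2, 5, 7)]
        flagged = flag_known_artifacts(regions, bl)
        assert sorted(r.region_id for r, _ in flagged) == ["R3", "R6", "R8"]
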