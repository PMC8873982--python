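"""Cleaning stage: sample QC, gap merging (vs brute-force oracle), length
cap, and cohort summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvrkit.cleaning import (
    CleanConfig,
    drop_long_cnvs,
    filter_samples_by_qc,
    merge_adjacent_calls,
    summarize_cnvs,
)
from cnvrkit.simulate import simulate_cohort
from cnvrkit.types import CnvCall, ConfigError, SampleQcRecord, SchemaError

from conftest import small_sim_config
from oracles import pairwise_merge_fixed_point


def qc(sid, lrr, drift, wave):
    return SampleQcRecord(sid, lrr, drift, wave)


class TestSampleQc:
    @pytest.mark.parametrize(
        "rec,kept,reason",
        [
            (qc("a", 0.29, 0.004, 0.05), True, None),
            (qc("b", 0.31, 0.001, 0.0), False, "LRR_SD"),
            (qc("c", 0.1, 0.006, 0.0), False, "BAF_DRIFT"),
            (qc("d", 0.1, 0.001, -0.15), False, "WAVE_FACTOR"),
            # thresholds are strict ("larger than"), so boundary values pass
            (qc("e", 0.30, 0.005, 0.1), True, None),
            (qc("f", 0.30, 0.005, -0.1), True, None),
        ],
    )
    def test_exclusion_rule(self, rec, kept, reason):
        kept_ids, excluded = filter_samples_by_qc([rec])
        assert (rec.sample_id in kept_ids) == kept
        if reason:
            assert reason in excluded[rec.sample_id]

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(SchemaError):
            filter_samples_by_qc([qc("a", 0.1, 0.001, 0), qc("a", 0.1, 0.001, 0)])


def call(start, end, sid="S1", cn=1, chrom="1", n_snp=3):
    return CnvCall(sid, chrom, start, end, cn, n_snp)


class TestMergeAdjacent:
    def test_small_gap_merges(self):
        # gap 100 over span 2000: ratio 0.05 < 0.2
        merged = merge_adjacent_calls([call(1, 1000), call(1101, 2000)], 0.2)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].n_snp) == (1, 2000, 6)

    def test_large_gap_stays(self):
        # gap 1000 over span 3000: ratio 0.333 >= 0.2
        merged = merge_adjacent_calls([call(1, 1000), call(2001, 3000)], 0.2)
        assert len(merged) == 2

    def test_different_states_never_merge(self):
        merged = merge_adjacent_calls([call(1, 1000, cn=1), call(1001, 2000, cn=3)], 0.2)
        assert len(merged) == 2

    def test_overlap_merges_unconditionally(self, caplog):
        with caplog.at_level("WARNING"):
            merged = merge_adjacent_calls([call(1, 1000), call(500, 2000)], 0.2)
        assert len(merged) == 1 and "overlapping" in caplog.text

    def test_conf_is_min_of_members(self):
        a = CnvCall("S1", "1", 1, 1000, 1, 3, conf=50.0)
        b = CnvCall("S1", "1", 1050, 2000, 1, 3, conf=20.0)
        (m,) = merge_adjacent_calls([a, b], 0.2)
        assert m.conf == 20.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_pairwise_oracle(self, data):
        n = data.draw(st.integers(1, 8))
        starts = sorted(data.draw(st.lists(
            st.integers(1, 5000), min_size=n, max_size=n, unique=True)))
        ivs = []
        for s in starts:
            length = data.draw(st.integers(1, 1500))
            ivs.append((s, s + length - 1))
        calls = [call(s, e) for s, e in ivs]
        got = sorted((c.start, c.end) for c in merge_adjacent_calls(calls, 0.2))
        assert got == pairwise_merge_fixed_point(ivs, 0.2)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 10_000), st.integers(1, 3000)),
                    min_size=1, max_size=12))
    def test_idempotent(self, raw):
        calls = [call(s, s + l - 1) for s, l in raw]
        once = merge_adjacent_calls(calls, 0.2)
        assert merge_adjacent_calls(once, 0.2) == once

    def test_total_coverage_only_grows_by_gap_bases(self):
        calls = [call(1, 1000), call(1101, 2000), call(5000, 6000)]
        merged = merge_adjacent_calls(calls, 0.2)
        before = sum(c.length for c in calls)
        after = sum(c.length for c in merged)
        assert after - before == 100  # exactly the swallowed gap


class TestDropLong:
    def test_boundary_is_strict(self):
        kept, dropped = drop_long_cnvs([call(1, 5_000_000), call(1, 5_000_001)], 5)
        assert [c.length for c in kept] == [5_000_000]
        assert [c.length for c in dropped] == [5_000_001]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        calls = [call(1, int(l)) for l in rng.integers(1, 10_000_000, size=50)]
        kept, dropped = drop_long_cnvs(calls, 5)
        assert sorted(kept + dropped, key=id) is not None
        assert len(kept) + len(dropped) == len(calls)
        assert set(map(id, kept)).isdisjoint(map(id, dropped))

    def test_simulated_oversize_artifacts_are_exactly_what_drops(self):
        cfg = small_sim_config(seed=9, oversize_artifact_frac=0.1, fp_call_rate=0.0)
        bundle = simulate_cohort(cfg)
        kept, dropped = drop_long_cnvs(bundle.penncnv_calls, 5)
        assert {c.key for c in dropped} == {
            k for k in bundle.truth.oversize_call_keys if k.startswith("penncnv")}


class TestSummary:
    def test_single_call(self):
        s = summarize_cnvs([call(1, 100)], n_individuals=4)
        assert s.n_cnvs == 1
        assert s.cnvs_per_individual == 0.25
        assert s.per_state_length_stats[1] == (100.0, 100, 100)

    def test_counts_sum_and_mean_consistency(self):
        rng = np.random.default_rng(1)
        calls = [call(1, int(l), cn=int(cn))
                 for l, cn in zip(rng.integers(100, 10_000, 200),
                                  rng.choice([0, 1, 3, 4], 200))]
        s = summarize_cnvs(calls, 25)
        assert sum(s.per_state_counts.values()) == s.n_cnvs == 200
        assert s.cnvs_per_individual * 25 == pytest.approx(s.n_cnvs)
        assert sum(s.length_bins.values()) == s.n_cnvs

    def test_zero_individuals_rejected(self):
        with pytest.raises(ConfigError):
            summarize_cnvs([call(1, 100)], 0)


def test_clean_config_validation():
    with pytest.raises(ConfigError):
        CleanConfig(merge_fraction=1.5)
    with pytest.raises(ConfigError):
        CleanConfig(drop_length_mb=0)
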