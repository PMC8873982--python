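"""Gene annotation, carrier-frequency thresholding, cross-assembly gene sets."""
import numpy as np
import pytest

from cnvrkit.compare import consensus_cnvrs, consensus_threshold
from cnvrkit.genes import (
    GeneHit,
    annotate_genes,
    compare_genes_across_builds,
    consensus_genes,
    gene_hits,
)
from cnvrkit.simulate import simulate_cohort
from cnvrkit.types import CnvCall, GeneRecord

from conftest import random_calls, small_sim_config
from oracles import gene_hit_pairs


def call(start, end, sid="S1", cn=1, chrom="1"):
    return CnvCall(sid, chrom, start, end, cn, 3)


def gene(name, start, end, chrom="1"):
    return GeneRecord(name, chrom, start, end)


class TestAnnotate:
    def test_inclusive_overlap_arithmetic(self):
        pairs = gene_hits([call(150, 300)], [gene("G", 100, 200)])
        assert len(pairs) == 1
        assert pairs[0][2] == 51  # bases 150..200 inclusive

    def test_adjacent_non_overlap(self):
        assert gene_hits([call(201, 300)], [gene("G", 100, 200)]) == []

    def test_aggregation_counts_distinct_samples(self):
        items = [call(100, 300, "S1"), call(100, 300, "S1"), call(100, 300, "S2")]
        (hit,) = annotate_genes(items, [gene("G", 150, 250)], cohort_size=10)
        assert (hit.n_cnvs, hit.n_samples) == (3, 2)
        assert hit.frequency_pct == pytest.approx(20.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            items = random_calls(rng, 30)
            genes = [gene(f"G{i}", s, s + 500, chrom=str(int(rng.integers(1, 3))))
                     for i, s in enumerate(rng.integers(1, 99_000, size=20))]
            got = {(g.gene_name, items.index(item))
                   for g, item, _ in gene_hits(items, genes)}
            assert got == gene_hit_pairs(genes, items)

    def test_order_invariance(self):
        rng = np.random.default_rng(18)
        items = random_calls(rng, 30)
        genes = [gene(f"G{i}", int(s), int(s) + 400)
                 for i, s in enumerate(rng.integers(1, 90_000, size=10))]
        a = annotate_genes(items, genes)
        perm = list(rng.permutation(len(items)))
        b = annotate_genes([items[i] for i in perm], list(reversed(genes)))
        assert a == b


class TestConsensusGenes:
    def _hit(self, name, n_samples):
        return GeneHit(name, "1", 100, n_samples + 1, n_samples, None)

    def test_boundary_inclusive(self):
        hits = [self._hit("keep", 20), self._hit("drop", 19)]
        assert [h.gene_name for h in consensus_genes(hits, 20)] == ["keep"]

    def test_sorted_by_frequency(self):
        hits = [self._hit("b", 25), self._hit("a", 40)]
        assert [h.gene_name for h in consensus_genes(hits, 20)] == ["a", "b"]

    def test_genes_inside_high_frequency_regions_pass(self):
        # genes planted inside >=5%-frequency regions pass; background
        # genes outside every planted region never do (fp calls disabled)
        cfg = small_sim_config(seed=41, fp_call_rate=0.0, qc_fail_frac=0.0)
        bundle = simulate_cohort(cfg)
        thr = consensus_threshold([cfg.n_samples], 0.05)
        calls = bundle.penncnv_calls + bundle.cnvpartition_calls
        hits = annotate_genes(calls, bundle.genes, cohort_size=cfg.n_samples)
        passed = {h.gene_name for h in consensus_genes(hits, thr)}
        rich = {p.index for p in bundle.truth.planted if p.n_carriers >= thr}
        for name, arch in bundle.truth.gene_archetype.items():
            if arch in rich:
                assert name in passed
            if arch is None:
                assert name not in passed

    def test_consensus_gene_lies_in_consensus_region_at_equal_threshold(self):
        cfg = small_sim_config(seed=43, fp_call_rate=0.0)
        bundle = simulate_cohort(cfg)
        thr = consensus_threshold([cfg.n_samples], 0.05)
        cs = consensus_cnvrs([bundle.penncnv_calls, bundle.cnvpartition_calls], thr)
        hits = annotate_genes(list(cs.union_regions), bundle.genes,
                              cohort_size=cfg.n_samples)
        keep = consensus_genes(hits, thr)
        consensus_ids = {r.region_id for r in cs.regions}
        for h in keep:
            assert set(h.item_ids) & consensus_ids, (
                f"{h.gene_name} passes the threshold but sits in no "
                "consensus region")


class TestCrossBuildComparison:
    def test_partition_and_union_size(self):
        a = {f"g{i}" for i in range(26)}                      # 26 genes
        b = {f"g{i}" for i in range(6, 26)} | {f"h{i}" for i in range(11)}
        comp = compare_genes_across_builds(a, b)
        assert (len(comp.shared), len(comp.a_only), len(comp.b_only)) == (20, 6, 11)
        assert comp.union_size == 37

    def test_identical_sets(self):
        comp = compare_genes_across_builds({"x", "y"}, {"X", "y"})
        assert comp.a_only == comp.b_only == frozenset()

    def test_synonym_mapping(self):
        comp = compare_genes_across_builds(
            {"LOC100848815"}, {"BOLA-DQA1"},
            synonyms={"LOC100848815": "BOLA-DQA1"})
        assert comp.shared == frozenset({"BOLA-DQA1"})

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(19)
        pool = [f"gene{i}" for i in range(50)]
        a = {g for g in pool if rng.random() < 0.5}
        b = {g for g in pool if rng.random() < 0.5}
        comp = compare_genes_across_builds(a, b)
        up = {n.upper() for n in a | b}
        assert comp.shared | comp.a_only | comp.b_only == up
        assert not (comp.shared & comp.a_only)
        assert not (comp.shared & comp.b_only)
        assert not (comp.a_only & comp.b_only)
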