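"""Cross-caller and cross-list comparison of CNVs and CNV regions.

Three levels of comparison are provided:

* **individual level** — a CNV in list A counts as overlapped only if some
  CNV in list B from the *same sample* shares >= 1 bp; this measures how
  similar two detection methods are call-for-call.
* **population level** — sample identity is ignored; this measures the
  repeatability of the region, and is therefore never lower than the
  individual-level percentage.
* **region level** — CNVR lists are intersected; overlapped length is the
  length of the union of pairwise intersections, so a basepair covered by
  several pairs is counted once.

Consensus CNVRs are obtained by pooling the calls from several callers,
re-running region generation on the pool, and keeping regions whose
distinct-sample carrier count reaches a cohort-proportion threshold
(default 5% of the smallest per-caller sample size, rounded up).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from ._utils import (
    ceil_decimal,
    merge_intervals,
    total_interval_length,
)
from .cnvr import call_cnvr
from .types import CnvCall, CnvError, CnvRegion

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapPair:
    """One >=1-bp intersection between a region/call in A and one in B."""

    a_id: str
    b_id: str
    overlap_bp: int
    frac_a: float
    frac_b: float
    state_match: str  # "same" | "different" | "n/a"

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise CnvError("OverlapPair requires >= 1 bp of overlap")


@dataclass(frozen=True)
class DirectionStats:
    """Overlap tally for one direction of a CNV comparison."""

    n_total: int
    n_overlapped: int
    n_same_state: int
    n_different_state: int

    @property
    def pct_overlapped(self) -> float:
        return 100.0 * self.n_overlapped / self.n_total if self.n_total else 0.0


@dataclass(frozen=True)
class CnvCompareReport:
    level: str  # "individual" | "population"
    a: DirectionStats
    b: DirectionStats


def _build_trees(calls: Sequence[CnvCall], by_sample: bool) -> Dict[tuple, IntervalTree]:
    trees: Dict[tuple, IntervalTree] = {}
    # data carries an index so identical duplicate calls stay distinct
    for i, c in enumerate(calls):
        key = (c.sample_id, c.chrom) if by_sample else (c.chrom,)
        trees.setdefault(key, IntervalTree())[c.start : c.end + 1] = (i, c)
    return trees


def _direction(a: Sequence[CnvCall], trees: Dict[tuple, IntervalTree],
               by_sample: bool) -> DirectionStats:
    n_hit = n_same = n_diff = 0
    for c in a:
        key = (c.sample_id, c.chrom) if by_sample else (c.chrom,)
        tree = trees.get(key)
        hits = tree.overlap(c.start, c.end + 1) if tree is not None else ()
        if not hits:
            continue
        n_hit += 1
        if any(iv.data[1].cn == c.cn for iv in hits):
            n_same += 1
        else:
            n_diff += 1
    return DirectionStats(len(a), n_hit, n_same, n_diff)


def _compare_cnv(a: Sequence[CnvCall], b: Sequence[CnvCall],
                 level: str) -> CnvCompareReport:
    if not a or not b:
        log.warning("CNV comparison with an empty list (%d vs %d calls)", len(a), len(b))
    by_sample = level == "individual"
    return CnvCompareReport(
        level=level,
        a=_direction(a, _build_trees(b, by_sample), by_sample),
        b=_direction(b, _build_trees(a, by_sample), by_sample),
    )


def compare_cnv_individual(a: Sequence[CnvCall], b: Sequence[CnvCall]) -> CnvCompareReport:
    """Per-direction overlap tallies requiring matching sample ids."""
    return _compare_cnv(a, b, "individual")


def compare_cnv_population(a: Sequence[CnvCall], b: Sequence[CnvCall]) -> CnvCompareReport:
    """Per-direction overlap tallies ignoring sample identity."""
    return _compare_cnv(a, b, "population")


@dataclass(frozen=True)
class CnvrCompareReport:
    """Region-level comparison of two CNVR lists."""

    n_a: int
    n_b: int
    n_a_hit: int
    n_b_hit: int
    overlap_bp: int           # union of pairwise intersections
    total_len_a: int
    total_len_b: int

    @property
    def pct_a_hit(self) -> float:
        return 100.0 * self.n_a_hit / self.n_a if self.n_a else 0.0

    @property
    def pct_b_hit(self) -> float:
        return 100.0 * self.n_b_hit / self.n_b if self.n_b else 0.0

    @property
    def pct_len_a(self) -> float:
        return 100.0 * self.overlap_bp / self.total_len_a if self.total_len_a else 0.0

    @property
    def pct_len_b(self) -> float:
        return 100.0 * self.overlap_bp / self.total_len_b if self.total_len_b else 0.0


def compare_cnvr(
    a: Sequence[CnvRegion], b: Sequence[CnvRegion]
) -> Tuple[List[OverlapPair], CnvrCompareReport]:
    """All >=1-bp intersecting region pairs plus a length-accounting report.

    The overlapped length is the basepair size of intersect(union(A),
    union(B)) per chromosome summed, so a region hit by several partners
    contributes each shared basepair once.
    """
    trees: Dict[str, IntervalTree] = {}
    for r in b:
        trees.setdefault(r.chrom, IntervalTree())[r.start : r.end + 1] = r
    pairs: List[OverlapPair] = []
    a_hit: set = set()
    b_hit: set = set()
    inter_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in a:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(r.start, r.end + 1)):
            rb: CnvRegion = iv.data
            s = max(r.start, rb.start)
            e = min(r.end, rb.end)
            pairs.append(
                OverlapPair(
                    a_id=r.region_id,
                    b_id=rb.region_id,
                    overlap_bp=e - s + 1,
                    frac_a=(e - s + 1) / r.length,
                    frac_b=(e - s + 1) / rb.length,
                    state_match="same" if r.type == rb.type else "different",
                )
            )
            a_hit.add(r.region_id)
            b_hit.add(rb.region_id)
            inter_by_chrom.setdefault(r.chrom, []).append((s, e))
    overlap_bp = sum(
        total_interval_length(merge_intervals(ivs))
        for ivs in inter_by_chrom.values()
    )
    report = CnvrCompareReport(
        n_a=len(a),
        n_b=len(b),
        n_a_hit=len(a_hit),
        n_b_hit=len(b_hit),
        overlap_bp=overlap_bp,
        total_len_a=sum(r.length for r in a),
        total_len_b=sum(r.length for r in b),
    )
    return pairs, report


def consensus_threshold(sample_sizes: Sequence[int], proportion: float = 0.05) -> int:
    """Carrier-count threshold: ceiling(min(sample sizes) x proportion).

    With per-result sample sizes whose minimum is 393 and the default 5%
    proportion this yields ceil(19.65) = 20.
    """
    if not sample_sizes:
        raise CnvError("sample_sizes must be non-empty")
    if any(n < 1 for n in sample_sizes):
        raise CnvError("all sample sizes must be >= 1")
    return ceil_decimal(min(sample_sizes), proportion)


@dataclass(frozen=True)
class ConsensusSet:
    """Consensus regions from a pooled multi-caller union set."""

    threshold_n: int
    source_lists: Tuple[str, ...]
    regions: Tuple[CnvRegion, ...]
    union_regions: Tuple[CnvRegion, ...] = ()

    def __post_init__(self) -> None:
        low = [r.region_id for r in self.regions if r.n_samples < self.threshold_n]
        if low:
            raise CnvError(f"regions below consensus threshold: {low}")


def consensus_cnvrs(
    call_lists: Sequence[Sequence[CnvCall]],
    threshold_n: int,
    *,
    source: str = "union",
    inclusive: bool = True,
) -> ConsensusSet:
    """Pool >= 2 call lists, regenerate regions, keep high-frequency ones.

    Distinct samples are counted once even when both callers report the
    same carrier.  ``inclusive`` selects ``>=`` (default) versus ``>`` for
    the threshold comparison.  All lists must share one genome build.
    """
    pooled: List[CnvCall] = [c for lst in call_lists for c in lst]
    builds = {c.build for c in pooled}
    if len(builds) > 1:
        raise CnvError(f"cannot pool calls from different builds: {sorted(builds)}")
    union = call_cnvr(pooled, source=source)
    if inclusive:
        keep = [r for r in union if r.n_samples >= threshold_n]
    else:
        keep = [r for r in union if r.n_samples > threshold_n]
    labels = tuple(sorted({c.caller for c in pooled}))
    return ConsensusSet(
        threshold_n=threshold_n,
        source_lists=labels,
        regions=tuple(keep),
        union_regions=tuple(union),
    )


@dataclass(frozen=True)
class DbCompareReport:
    """Cross-validation of study regions against an external CNVR list."""

    n_study: int
    n_study_hit: int
    n_external_hit: int
    n_study_specific: int
    overlap_bp: int
    total_study_bp: int

    @property
    def pct_study_hit(self) -> float:
        return 100.0 * self.n_study_hit / self.n_study if self.n_study else 0.0

    @property
    def pct_study_len(self) -> float:
        return 100.0 * self.overlap_bp / self.total_study_bp if self.total_study_bp else 0.0


def compare_to_database(
    study: Sequence[CnvRegion], external: Sequence[CnvRegion]
) -> DbCompareReport:
    """Count study regions validated by (>=1 bp hit in) an external list."""
    _, rep = compare_cnvr(study, external)
    return DbCompareReport(
        n_study=rep.n_a,
        n_study_hit=rep.n_a_hit,
        n_external_hit=rep.n_b_hit,
        n_study_specific=rep.n_a - rep.n_a_hit,
        overlap_bp=rep.overlap_bp,
        total_study_bp=rep.total_len_a,
    )


def flag_known_artifacts(
    study: Sequence[CnvRegion],
    blacklist: Sequence[Tuple[str, int, int, str]],
) -> List[Tuple[CnvRegion, str]]:
    """Flag study regions intersecting known false-positive intervals.

    ``blacklist`` entries are (chrom, start, end, id) tuples, e.g. regions
    attributable to reference-assembly errors.  Returns (region,
    blacklist id) pairs; a region hitting several intervals is flagged once
    per interval.
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end, bid in blacklist:
        trees.setdefault(str(chrom), IntervalTree())[start : end + 1] = bid
    flagged: List[Tuple[CnvRegion, str]] = []
    for r in study:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(r.start, r.end + 1)):
            flagged.append((r, iv.data))
    return flagged
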