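"""CNV region (CNVR) generation, classification and summary.

A CNVR is a connected component of the interval-overlap graph of CNV calls
on one chromosome, where overlap means at least one shared basepair
(A.start <= B.end and B.start <= A.end).  Calls that merely touch
end-to-start (gap of zero bases between them) are *not* merged.  A region
is a gain if every member call has copy number > 2, a loss if every member
has copy number < 2, and mixed otherwise.  The carrier frequency of a
region is its number of distinct samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from ._utils import chrom_sort_key, merge_intervals, round_report, total_interval_length
from .types import (
    GAIN,
    LOSS,
    MIXED,
    CnvCall,
    CnvError,
    CnvRegion,
    GenomeBuild,
)


def classify_cnv_states(cns: Sequence[int]) -> str:
    """gain iff all copy numbers > 2; loss iff all < 2; mixed otherwise."""
    if not cns:
        raise CnvError("cannot classify an empty region")
    if any(cn == 2 for cn in cns):
        raise CnvError("copy number 2 is not a CNV state")
    if all(cn > 2 for cn in cns):
        return GAIN
    if all(cn < 2 for cn in cns):
        return LOSS
    return MIXED


def classify_cnvr(region: CnvRegion) -> str:
    """Re-derive a region's type from its member calls."""
    return classify_cnv_states([c.cn for c in region.member_calls])


def call_cnvr(
    calls: Sequence[CnvCall],
    *,
    source: str = "",
    id_prefix: str = "CNVR",
    genome: Optional[GenomeBuild] = None,
) -> List[CnvRegion]:
    """Merge calls that overlap by >= 1 bp into population CNV regions.

    Regions are numbered ``CNVR_1 .. CNVR_n`` in (chromosome, start) order.
    The result is independent of the input order of ``calls``.  When a
    ``genome`` is given, calls on chromosomes absent from it raise
    :class:`CnvError` listing the offenders.
    """
    if genome is not None:
        bad = sorted({c.chrom for c in calls if c.chrom not in genome})
        if bad:
            raise CnvError(f"calls on chromosomes absent from genome: {bad}")
    by_chrom: Dict[str, List[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    raw: List[Tuple[str, int, int, List[CnvCall]]] = []
    for chrom, group in by_chrom.items():
        group.sort(key=lambda c: (c.start, c.end, c.sample_id, c.caller))
        members: List[CnvCall] = [group[0]]
        cur_end = group[0].end
        start = group[0].start
        for c in group[1:]:
            if c.start <= cur_end:  # >= 1 shared bp
                members.append(c)
                cur_end = max(cur_end, c.end)
            else:
                raw.append((chrom, start, cur_end, members))
                members = [c]
                start, cur_end = c.start, c.end
        raw.append((chrom, start, cur_end, members))

    raw.sort(key=lambda t: (chrom_sort_key(t[0]), t[1], t[2]))
    regions = []
    for k, (chrom, start, end, members) in enumerate(raw, start=1):
        regions.append(
            CnvRegion(
                region_id=f"{id_prefix}_{k}",
                chrom=chrom,
                start=start,
                end=end,
                type=classify_cnv_states([m.cn for m in members]),
                member_calls=tuple(members),
                n_samples=len({m.sample_id for m in members}),
                n_calls=len(members),
                source=source,
            )
        )
    return regions


@dataclass(frozen=True)
class TypeStats:
    count: int
    mean_length: float
    min_length: int
    max_length: int
    total_length: int


@dataclass(frozen=True)
class CnvrSummary:
    """Per-type region statistics plus genome coverage."""

    per_type: Mapping[str, TypeStats]
    total_count: int
    total_length_bp: int
    genome_coverage_pct: float
    per_chrom_coverage_pct: Mapping[str, float]

    def to_rows(self) -> List[dict]:
        rows = []
        for t in (GAIN, LOSS, MIXED):
            if t not in self.per_type:
                continue
            s = self.per_type[t]
            rows.append(
                {
                    "type": t,
                    "n_regions": s.count,
                    "mean_length": round_report(s.mean_length, 0),
                    "min_length": s.min_length,
                    "max_length": s.max_length,
                    "total_length": s.total_length,
                }
            )
        rows.append(
            {
                "type": "total",
                "n_regions": self.total_count,
                "mean_length": "",
                "min_length": "",
                "max_length": "",
                "total_length": self.total_length_bp,
            }
        )
        return rows


def cnvr_summary(regions: Sequence[CnvRegion], genome: GenomeBuild) -> CnvrSummary:
    """Summarise regions by type and compute genome coverage.

    Coverage is 100 x (sum of region lengths) / (sum of chromosome lengths
    in ``genome``); per-chromosome coverage uses the union of regions on
    the chromosome so overlapping inputs are not double-counted.
    """
    bad = sorted({r.chrom for r in regions if r.chrom not in genome})
    if bad:
        raise CnvError(f"regions on chromosomes absent from genome: {bad}")
    per_type: Dict[str, List[int]] = {}
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        per_type.setdefault(r.type, []).append(r.length)
        by_chrom.setdefault(r.chrom, []).append(r.interval)
    stats = {
        t: TypeStats(
            count=len(v),
            mean_length=sum(v) / len(v),
            min_length=min(v),
            max_length=max(v),
            total_length=sum(v),
        )
        for t, v in per_type.items()
    }
    total_len = sum(r.length for r in regions)
    per_chrom = {
        chrom: 100.0 * total_interval_length(merge_intervals(ivs)) / genome.chrom_lengths[chrom]
        for chrom, ivs in by_chrom.items()
    }
    return CnvrSummary(
        per_type=stats,
        total_count=len(regions),
        total_length_bp=total_len,
        genome_coverage_pct=100.0 * total_len / genome.total_length,
        per_chrom_coverage_pct=per_chrom,
    )
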