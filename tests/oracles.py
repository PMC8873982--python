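"""Independent brute-force oracles used to check the fast implementations.

Everything here works at basepair or all-pairs resolution on small inputs
and deliberately shares no code with the package's sweep/tree algorithms.
"""
from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from cnvrkit.types import CnvCall, CnvRegion


def bp_regions(calls: Sequence[CnvCall], chrom_len: int) -> Dict[str, List[Tuple[int, int]]]:
    """Maximal covered runs per chromosome, from a coverage array.

    Coverage is marked on a doubled grid (basepair b occupies position 2b)
    so that two closed intervals that touch end-to-start — sharing no
    basepair — leave an unmarked odd position between them and stay
    separate runs, matching the ">= 1 shared bp" merge rule exactly.
    """
    out: Dict[str, List[Tuple[int, int]]] = {}
    chroms = sorted({c.chrom for c in calls})
    for chrom in chroms:
        cov = np.zeros(2 * chrom_len + 4, dtype=np.int8)
        for c in calls:
            if c.chrom == chrom:
                cov[2 * c.start : 2 * c.end + 1] = 1
        d = np.diff(cov)
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1)
        out[chrom] = [(int(s) // 2, int(e) // 2) for s, e in zip(starts, ends)]
    return out


def bp_overlap_length(a: Sequence[CnvRegion], b: Sequence[CnvRegion],
                      chrom_len: int) -> int:
    """Basepairs covered by both lists, from boolean coverage arrays."""
    total = 0
    for chrom in sorted({r.chrom for r in a} | {r.chrom for r in b}):
        cov_a = np.zeros(chrom_len + 2, dtype=bool)
        cov_b = np.zeros(chrom_len + 2, dtype=bool)
        for r in a:
            if r.chrom == chrom:
                cov_a[r.start : r.end + 1] = True
        for r in b:
            if r.chrom == chrom:
                cov_b[r.start : r.end + 1] = True
        total += int((cov_a & cov_b).sum())
    return total


def pairwise_merge_fixed_point(
    intervals: Sequence[Tuple[int, int]], fraction: float
) -> List[Tuple[int, int]]:
    """Exhaustive any-pair gap merging to a fixed point (span denominator).

    Repeatedly scans all pairs and merges the first mergeable one
    (overlapping, or gap/span < fraction) until no pair qualifies.
    """
    ivs = sorted(intervals)
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(len(ivs)):
                if i == j:
                    continue
                a, b = sorted((ivs[i], ivs[j]))
                gap = b[0] - a[1] - 1
                span = max(a[1], b[1]) - a[0] + 1
                if gap < 0 or gap / span < fraction:
                    merged = (a[0], max(a[1], b[1]))
                    ivs = [iv for k, iv in enumerate(ivs) if k not in (i, j)]
                    ivs.append(merged)
                    ivs.sort()
                    changed = True
                    break
            if changed:
                break
    return ivs


def overlap_counts(a: Sequence[CnvCall], b: Sequence[CnvCall],
                   same_sample: bool) -> int:
    """All-pairs count of calls in A overlapped by >= 1 call in B."""
    n = 0
    for ca in a:
        for cb in b:
            if same_sample and ca.sample_id != cb.sample_id:
                continue
            if ca.chrom == cb.chrom and ca.start <= cb.end and cb.start <= ca.end:
                n += 1
                break
    return n


def gene_hit_pairs(genes, items) -> set:
    """All-pairs (gene, item index) intersections."""
    out = set()
    for g in genes:
        for i, item in enumerate(items):
            if g.chrom == item.chrom and g.tx_start <= item.end and item.start <= g.tx_end:
                out.add((g.gene_name, i))
    return out


def discordant_pairs_bruteforce(ranks: Sequence[int]) -> int:
    n = 0
    for i in range(len(ranks)):
        for j in range(i + 1, len(ranks)):
            if ranks[i] > ranks[j]:
                n += 1
    return n


def jaccard(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union
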