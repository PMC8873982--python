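"""Small shared helpers: interval set algebra, report rounding, sorting."""
from __future__ import annotations

import math
from decimal import ROUND_CEILING, ROUND_HALF_UP, Decimal
from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]  # 1-based, closed


def round_report(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed report values (9.495 -> 9.50)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def ceil_decimal(value: int, proportion: float) -> int:
    """Ceiling of ``value * proportion`` with exact decimal arithmetic.

    Avoids float artefacts such as 400 * 0.05 == 20.000000000000004 rounding
    up to 21.
    """
    d = Decimal(value) * Decimal(str(proportion))
    return int(d.to_integral_value(rounding=ROUND_CEILING))


def chrom_sort_key(label: str):
    """Sort numeric chromosome labels numerically, others lexically after."""
    try:
        return (0, int(label), "")
    except (TypeError, ValueError):
        return (1, 0, str(label))


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of 1-based closed intervals; adjacent intervals are coalesced.

    Used only for length accounting, where coalescing touching intervals
    does not change the total.
    """
    ivs = sorted(intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_interval_sets(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Intersection of two interval unions (inputs need not be disjoint)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_interval_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def count_inversions(seq: Sequence[int]) -> int:
    """Number of discordant (out-of-order) pairs, by merge sort, O(n log n)."""
    def rec(s: List[int]) -> Tuple[List[int], int]:
        if len(s) <= 1:
            return s, 0
        mid = len(s) // 2
        left, nl = rec(s[:mid])
        right, nr = rec(s[mid:])
        merged: List[int] = []
        inv = nl + nr
        i = j = 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i])
                i += 1
            else:
                merged.append(right[j])
                j += 1
                inv += len(left) - i
        merged.extend(left[i:])
        merged.extend(right[j:])
        return merged, inv

    return rec(list(seq))[1]


def mean(xs: Sequence[float]) -> float:
    if not xs:
        return math.nan
    return sum(xs) / len(xs)
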