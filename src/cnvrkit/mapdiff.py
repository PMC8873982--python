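"""Comparison of two SNP manifests of one array across genome assemblies.

Every marker name in the union of the two maps falls in exactly one of
seven categories: same chromosome in both, different chromosomes, unknown
position in both, unknown in A only, unknown in B only, missing from A, or
missing from B.  "Same chromosome" does not require equal positions —
position and order disagreement is summarised separately as a
Kendall-style discordant-pair count per chromosome.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from ._utils import chrom_sort_key, count_inversions
from .types import GenomeBuild, SnpMarker

log = logging.getLogger(__name__)

CATEGORIES = (
    "same_chromosome",
    "both_unknown",
    "different_chromosomes",
    "unknown_in_a",
    "unknown_in_b",
    "missing_from_a",
    "missing_from_b",
)


@dataclass(frozen=True)
class MapComparison:
    """Category counts plus per-map percentage denominators."""

    counts: Mapping[str, int]
    n_markers_a: int
    n_markers_b: int
    by_marker: Mapping[str, str] = field(default_factory=dict)

    def pct_in_a(self, category: str) -> float:
        """Category size as % of map A (0 for markers absent from A)."""
        if category == "missing_from_a" or self.n_markers_a == 0:
            return 0.0
        return 100.0 * self.counts[category] / self.n_markers_a

    def pct_in_b(self, category: str) -> float:
        if category == "missing_from_b" or self.n_markers_b == 0:
            return 0.0
        return 100.0 * self.counts[category] / self.n_markers_b

    def to_rows(self) -> List[dict]:
        labels = {
            "same_chromosome": "Same chromosome",
            "both_unknown": "Both unknown chromosomes",
            "different_chromosomes": "Different chromosomes",
            "unknown_in_a": "Unknown chromosome in A map",
            "unknown_in_b": "Unknown chromosome in B map",
            "missing_from_a": "Not found in A map",
            "missing_from_b": "Not found in B map",
        }
        return [
            {
                "category": labels[c],
                "n_snps": self.counts[c],
                "pct_in_a": round(self.pct_in_a(c), 1),
                "pct_in_b": round(self.pct_in_b(c), 1),
            }
            for c in CATEGORIES
        ]


def classify_marker_pairs(
    map_a: Sequence[SnpMarker], map_b: Sequence[SnpMarker]
) -> MapComparison:
    """Assign every marker in the union of the two maps to one category."""
    a = {m.name: m for m in map_a}
    b = {m.name: m for m in map_b}
    counts = {c: 0 for c in CATEGORIES}
    by_marker: Dict[str, str] = {}
    for name in a.keys() | b.keys():
        ma = a.get(name)
        mb = b.get(name)
        if ma is None:
            cat = "missing_from_a"
        elif mb is None:
            cat = "missing_from_b"
        elif not ma.is_mapped and not mb.is_mapped:
            cat = "both_unknown"
        elif not ma.is_mapped:
            cat = "unknown_in_a"
        elif not mb.is_mapped:
            cat = "unknown_in_b"
        elif ma.chrom == mb.chrom:
            cat = "same_chromosome"
        else:
            cat = "different_chromosomes"
        counts[cat] += 1
        by_marker[name] = cat
    return MapComparison(
        counts=counts,
        n_markers_a=len(a),
        n_markers_b=len(b),
        by_marker=by_marker,
    )


def snp_density(
    markers: Sequence[SnpMarker],
    genome: Optional[GenomeBuild] = None,
) -> Dict[str, float]:
    """Mapped markers per Mb for each chromosome.

    Chromosome lengths come from ``genome`` when given; otherwise the last
    marker position on each chromosome is used as a proxy (flagged with a
    warning because it slightly inflates density).  Chromosomes present in
    ``genome`` but without mapped markers get density 0.
    """
    by_chrom: Dict[str, List[int]] = {}
    for m in markers:
        if m.is_mapped:
            by_chrom.setdefault(m.chrom, []).append(m.pos)
    if genome is None:
        log.warning("snp_density: no genome given; using last marker position "
                    "as chromosome length proxy")
        lengths = {c: max(pos) for c, pos in by_chrom.items()}
    else:
        lengths = dict(genome.chrom_lengths)
    density: Dict[str, float] = {}
    for chrom in sorted(lengths, key=chrom_sort_key):
        n = len(by_chrom.get(chrom, ()))
        if n == 0:
            log.warning("snp_density: chromosome %s has no mapped markers", chrom)
            density[chrom] = 0.0
        else:
            density[chrom] = n / (lengths[chrom] / 1_000_000)
    return density


@dataclass(frozen=True)
class ChromConcordance:
    """Order agreement of shared markers on one chromosome."""

    chrom: str
    names: Tuple[str, ...]          # markers ordered by position in A
    ranks_b: Tuple[int, ...]        # their position ranks in B
    pos_a: Tuple[int, ...]
    pos_b: Tuple[int, ...]
    n_discordant_pairs: int

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def discordance(self) -> float:
        """Discordant pairs as a fraction of all marker pairs (0 = same order)."""
        n = self.n_markers
        n_pairs = n * (n - 1) // 2
        return self.n_discordant_pairs / n_pairs if n_pairs else 0.0


@dataclass(frozen=True)
class ConcordanceReport:
    per_chrom: Mapping[str, ChromConcordance]
    cross_chromosome: Tuple[str, ...]  # shared markers mapped to different chroms

    @property
    def total_discordant_pairs(self) -> int:
        return sum(c.n_discordant_pairs for c in self.per_chrom.values())


def position_concordance(
    map_a: Sequence[SnpMarker], map_b: Sequence[SnpMarker]
) -> ConcordanceReport:
    """Paired position ranks and discordant-pair counts per shared chromosome.

    Restricted to markers mapped in both maps; markers landing on different
    chromosomes are listed separately for plotting.  A discordant pair is a
    pair of same-chromosome markers whose relative order flips between the
    maps (counted exactly, via an inversion count on the rank sequence).
    """
    b = {m.name: m for m in map_b if m.is_mapped}
    shared: Dict[str, List[Tuple[int, int, str]]] = {}
    cross: List[str] = []
    for ma in map_a:
        if not ma.is_mapped:
            continue
        mb = b.get(ma.name)
        if mb is None:
            continue
        if ma.chrom == mb.chrom:
            shared.setdefault(ma.chrom, []).append((ma.pos, mb.pos, ma.name))
        else:
            cross.append(ma.name)
    per_chrom: Dict[str, ChromConcordance] = {}
    for chrom in sorted(shared, key=chrom_sort_key):
        rows = sorted(shared[chrom])  # by position in A; ties broken by B pos
        pos_b = [p_b for _, p_b, _ in rows]
        order_b = sorted(range(len(rows)), key=lambda i: (pos_b[i], i))
        ranks_b = [0] * len(rows)
        for rank, i in enumerate(order_b):
            ranks_b[i] = rank
        per_chrom[chrom] = ChromConcordance(
            chrom=chrom,
            names=tuple(name for _, _, name in rows),
            ranks_b=tuple(ranks_b),
            pos_a=tuple(p for p, _, _ in rows),
            pos_b=tuple(pos_b),
            n_discordant_pairs=count_inversions(ranks_b),
        )
    return ConcordanceReport(per_chrom=per_chrom, cross_chromosome=tuple(sorted(cross)))
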