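"""Gene annotation of CNVs/CNVRs, gene carrier frequency, consensus genes.

A gene is "hit" when it shares at least one basepair with a CNV call or
region.  The per-gene frequency is the number of *distinct samples* whose
calls intersect the gene (the raw call count is also kept); consensus
genes are those whose carrier count reaches the same cohort-proportion
threshold used for consensus CNVRs.  Because gene names are stable across
genome assemblies while coordinates are not, gene sets are the unit of
cross-assembly comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from intervaltree import IntervalTree

from ._utils import chrom_sort_key
from .types import CnvCall, CnvRegion, GeneRecord

Item = Union[CnvCall, CnvRegion]


def _item_id(item: Item) -> str:
    return item.region_id if isinstance(item, CnvRegion) else item.key


def _item_samples(item: Item) -> Set[str]:
    if isinstance(item, CnvRegion):
        return {c.sample_id for c in item.member_calls}
    return {item.sample_id}


@dataclass(frozen=True)
class GeneHit:
    """A gene with the CNV calls/regions intersecting it, aggregated."""

    gene_name: str
    chrom: str
    overlap_bp: int               # summed over intersecting items
    n_cnvs: int                   # intersecting calls (or regions)
    n_samples: int                # distinct carriers among those calls
    frequency_pct: Optional[float]  # 100 * n_samples / cohort size, if known
    item_ids: Tuple[str, ...] = ()


def gene_hits(
    items: Sequence[Item], genes: Sequence[GeneRecord]
) -> List[Tuple[GeneRecord, Item, int]]:
    """Every (gene, item) pair sharing >= 1 bp, with the shared length."""
    trees: Dict[str, IntervalTree] = {}
    # data carries the item index so identical duplicate calls stay distinct
    for i, item in enumerate(items):
        trees.setdefault(item.chrom, IntervalTree())[item.start : item.end + 1] = (i, item)
    out: List[Tuple[GeneRecord, Item, int]] = []
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(g.tx_start, g.tx_end + 1)):
            item: Item = iv.data[1]
            ov = min(g.tx_end, item.end) - max(g.tx_start, item.start) + 1
            out.append((g, item, ov))
    return out


def annotate_genes(
    items: Sequence[Item],
    genes: Sequence[GeneRecord],
    *,
    cohort_size: Optional[int] = None,
) -> List[GeneHit]:
    """Aggregate gene x CNV intersections into one record per hit gene.

    ``items`` may be raw calls or merged regions; for regions the carrier
    set is the union of member-call samples.  Genes intersecting nothing
    are omitted.  Output is sorted by carrier count (descending), then by
    genome position, so the most frequent genes come first.
    """
    agg: Dict[Tuple[str, str], dict] = {}
    for g, item, ov in gene_hits(items, genes):
        key = (g.gene_name, g.chrom)
        rec = agg.setdefault(
            key, {"overlap_bp": 0, "n_cnvs": 0, "samples": set(), "ids": [],
                  "start": g.tx_start},
        )
        rec["overlap_bp"] += ov
        rec["n_cnvs"] += 1
        rec["samples"] |= _item_samples(item)
        rec["ids"].append(_item_id(item))
    hits = [
        GeneHit(
            gene_name=name,
            chrom=chrom,
            overlap_bp=rec["overlap_bp"],
            n_cnvs=rec["n_cnvs"],
            n_samples=len(rec["samples"]),
            frequency_pct=(100.0 * len(rec["samples"]) / cohort_size
                           if cohort_size else None),
            item_ids=tuple(rec["ids"]),
        )
        for (name, chrom), rec in agg.items()
    ]
    hits.sort(key=lambda h: (-h.n_samples, chrom_sort_key(h.chrom), h.gene_name))
    return hits


def consensus_genes(
    hits: Sequence[GeneHit], threshold_n: int, *, inclusive: bool = True
) -> List[GeneHit]:
    """Genes carried by at least ``threshold_n`` distinct samples.

    The same threshold (ceiling of 5% of the smallest sample size by
    default) is used for consensus CNVRs, which keeps the two consensus
    definitions consistent.
    """
    if inclusive:
        keep = [h for h in hits if h.n_samples >= threshold_n]
    else:
        keep = [h for h in hits if h.n_samples > threshold_n]
    return sorted(keep, key=lambda h: (-h.n_samples, chrom_sort_key(h.chrom), h.gene_name))


@dataclass(frozen=True)
class GeneSetComparison:
    shared: frozenset
    a_only: frozenset
    b_only: frozenset

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.a_only) + len(self.b_only)


def compare_genes_across_builds(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    *,
    synonyms: Optional[Mapping[str, str]] = None,
) -> GeneSetComparison:
    """Partition two gene-name sets into shared / A-only / B-only.

    Names are compared case-insensitively; an optional synonym map
    (alias -> canonical name) is applied first so loci catalogued under
    provisional identifiers in one assembly can still be matched.
    """
    def canon(name: str) -> str:
        if synonyms:
            name = synonyms.get(name, name)
        return name.upper()

    a = {canon(n) for n in genes_a}
    b = {canon(n) for n in genes_b}
    return GeneSetComparison(
        shared=frozenset(a & b),
        a_only=frozenset(a - b),
        b_only=frozenset(b - a),
    )
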