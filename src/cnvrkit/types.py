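"""Shared domain types for SNP-array CNV post-analysis.

Coordinates are 1-based, closed intervals throughout (the convention of
PennCNV and the GenomeStudio/CNVPartition exports being parsed); BED output
converts to 0-based half-open on write.  Chromosome labels are bare strings
without a ``chr`` prefix; sex chromosomes are rejected by the readers by
default because the analysis runs on autosomes only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

#: copy-number states a CNV call may carry (2 == diploid is not a CNV)
VALID_CN = frozenset((0, 1, 3, 4))

GAIN = "gain"
LOSS = "loss"
MIXED = "mixed"
REGION_TYPES = (GAIN, LOSS, MIXED)

PENNCNV = "penncnv"
CNVPARTITION = "cnvpartition"


class CnvError(ValueError):
    """Base class for all domain errors raised by cnvrkit."""


class ParseError(CnvError):
    """A line or row of an input file could not be interpreted."""


class SchemaError(CnvError):
    """An input table is missing required columns or contains duplicates."""


class ConfigError(CnvError):
    """A configuration value is out of its admissible range."""


@dataclass(frozen=True)
class GenomeBuild:
    """A genome assembly: a name plus per-chromosome lengths.

    ``chrom_lengths`` lists the chromosomes the analysis runs on (for cattle
    SNP-array work, the 29 autosomes); the sum of its values is the
    denominator for genome-coverage percentages.
    """

    name: str
    chrom_lengths: Mapping[str, int]
    n_autosomes: int = 29

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_lengths", dict(self.chrom_lengths))
        if not self.name:
            raise ConfigError("genome build needs a name")
        if not self.chrom_lengths:
            raise ConfigError("genome build needs at least one chromosome")
        bad = {c: n for c, n in self.chrom_lengths.items() if n <= 0}
        if bad:
            raise ConfigError(f"non-positive chromosome lengths: {bad}")
        if self.n_autosomes < 1:
            raise ConfigError("n_autosomes must be >= 1")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class SnpMarker:
    """One array marker under one assembly.

    ``chrom``/``pos`` are ``None`` when the marker has no usable position in
    the map (chromosome 0/NA/Un or position 0 in the source file).
    """

    name: str
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("marker name must be non-empty")
        if (self.chrom is None) != (self.pos is None):
            raise ConfigError(
                f"marker {self.name}: chrom and pos must be unknown together"
            )
        if self.pos is not None and self.pos < 1:
            raise ConfigError(f"marker {self.name}: known position must be >= 1")

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None


@dataclass(frozen=True)
class CnvCall:
    """One CNV event in one sample, as reported by a caller."""

    sample_id: str
    chrom: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    cn: int
    n_snp: int = 1
    conf: Optional[float] = None
    caller: str = PENNCNV
    build: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )
        if self.cn not in VALID_CN:
            raise ConfigError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                f"copy number {self.cn} not in {sorted(VALID_CN)}"
            )
        if self.n_snp < 1:
            raise ConfigError("n_snp must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_gain(self) -> bool:
        return self.cn > 2

    @property
    def key(self) -> str:
        """Stable identifier used in comparison reports."""
        return f"{self.caller}:{self.sample_id}:{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SampleQcRecord:
    """Per-sample signal-quality statistics (computed upstream by PennCNV)."""

    sample_id: str
    lrr_sd: float
    baf_drift: float
    wave_factor: float

    def __post_init__(self) -> None:
        if self.lrr_sd < 0:
            raise ConfigError(f"{self.sample_id}: lrr_sd must be >= 0")
        if self.baf_drift < 0:
            raise ConfigError(f"{self.sample_id}: baf_drift must be >= 0")


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval from a refGene-style annotation table.

    Transcript rows of the same gene on the same chromosome are collapsed to
    the union interval by the reader, so one record spans the whole locus.
    """

    gene_name: str
    chrom: str
    tx_start: int  # 1-based, inclusive
    tx_end: int    # 1-based, inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.gene_name:
            raise ConfigError("gene_name must be non-empty")
        if self.tx_start >= self.tx_end:
            raise ConfigError(
                f"gene {self.gene_name}: tx_start must be < tx_end "
                f"({self.tx_start} >= {self.tx_end})"
            )

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start + 1


@dataclass(frozen=True)
class CnvRegion:
    """A population-level CNV region: the union of >=1-bp-overlapping calls.

    ``n_samples`` counts distinct carriers (the "frequency" used by all
    consensus thresholds); ``n_calls`` counts member calls.  Regions read
    back from files carry empty ``member_calls``.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    type: str
    member_calls: Tuple[CnvCall, ...] = field(default=())
    n_samples: int = 1
    n_calls: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"region {self.region_id}: start > end")
        if self.type not in REGION_TYPES:
            raise ConfigError(
                f"region {self.region_id}: type {self.type!r} not in {REGION_TYPES}"
            )
        if self.n_samples > self.n_calls:
            raise ConfigError(
                f"region {self.region_id}: n_samples ({self.n_samples}) exceeds "
                f"n_calls ({self.n_calls})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)
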