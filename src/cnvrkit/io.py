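"""Readers and writers for every external format the pipeline touches.

Formats handled
---------------
* PennCNV ``rawcnv`` text (one call per line)
* CNVPartition / GenomeStudio tab-separated CNV export
* three-column SNP map files (SNP Name, Chromosome, Position)
* UCSC refGene-style gene annotation tables
* per-sample signal-QC tables (LRR SD, BAF drift, wave factor)
* BED6 + TSV sidecar output for CNV regions
* two-column genome files (chromosome, length)

All parsed coordinates are 1-based closed; refGene transcription starts
(0-based in UCSC dumps) and BED output are converted at the boundary.
"""
from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ._utils import chrom_sort_key
from .types import (
    CNVPARTITION,
    PENNCNV,
    VALID_CN,
    CnvCall,
    CnvRegion,
    GeneRecord,
    GenomeBuild,
    ParseError,
    SampleQcRecord,
    SchemaError,
    SnpMarker,
)

log = logging.getLogger(__name__)

#: chromosome labels treated as "position unknown" in SNP maps (configurable)
UNKNOWN_CHROMS = ("0", "", "NA", "na", "nan")

#: sex chromosomes are not part of the autosome-only analysis
SEX_CHROMS = ("X", "Y", "x", "y", "MT", "M")

# PennCNV HMM state number for each copy number (state3/4 are diploid)
_STATE_BY_CN = {0: 1, 1: 2, 3: 5, 4: 6}

_PENNCNV_RE = re.compile(
    r"^(?:chr)?(?P<chrom>[^\s:]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)"
    r"\s+numsnp=(?P<numsnp>[\d,]+)"
    r"\s+length=(?P<length>[\d,]+)"
    r"\s+state(?P<state>\d+),cn=(?P<cn>\d+)"
    r"\s+(?P<file>\S+)"
    r"(?P<rest>.*)$"
)
_CONF_RE = re.compile(r"conf=(?P<conf>[-+0-9.eE]+)")


def _norm_chrom(label: str) -> str:
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


def _sample_from_path(field: str) -> str:
    base = os.path.basename(field)
    for ext in (".txt", ".gz", ".tsv", ".csv"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    return base


def read_penncnv_calls(
    path: str | Path,
    build: str = "",
    *,
    keep_sex_chroms: bool = False,
) -> List[CnvCall]:
    """Parse a PennCNV ``rawcnv`` output file into :class:`CnvCall` records.

    Lines with copy number 2 (diploid, not a CNV) are rejected with a
    warning; a malformed line raises :class:`ParseError` naming its line
    number.  The ``length=`` field is cross-checked against ``end-start+1``.
    """
    calls: List[CnvCall] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    n_seen = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        n_seen += 1
        m = _PENNCNV_RE.match(line.strip())
        if m is None:
            raise ParseError(f"{path}: line {lineno}: not a PennCNV rawcnv line")
        chrom = _norm_chrom(m["chrom"])
        if not keep_sex_chroms and chrom in SEX_CHROMS:
            log.warning("%s: line %d: sex chromosome %s skipped", path, lineno, chrom)
            continue
        cn = int(m["cn"])
        if cn not in VALID_CN:
            log.warning("%s: line %d: rejected record with cn=%d", path, lineno, cn)
            continue
        start = int(m["start"].replace(",", ""))
        end = int(m["end"].replace(",", ""))
        length = int(m["length"].replace(",", ""))
        if length != end - start + 1:
            log.warning(
                "%s: line %d: length field %d != end-start+1 (%d)",
                path, lineno, length, end - start + 1,
            )
        conf_m = _CONF_RE.search(m["rest"])
        calls.append(
            CnvCall(
                sample_id=_sample_from_path(m["file"]),
                chrom=chrom,
                start=start,
                end=end,
                cn=cn,
                n_snp=int(m["numsnp"].replace(",", "")),
                conf=float(conf_m["conf"]) if conf_m else None,
                caller=PENNCNV,
                build=build,
            )
        )
    if n_seen == 0:
        log.warning("%s: no CNV lines found (empty file)", path)
    return calls


def write_penncnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in PennCNV rawcnv layout (the inverse of the reader)."""
    with open(path, "w") as fh:
        for c in calls:
            state = _STATE_BY_CN[c.cn]
            conf = f"\tconf={c.conf:.3f}" if c.conf is not None else ""
            fh.write(
                f"chr{c.chrom}:{c.start}-{c.end}\tnumsnp={c.n_snp}"
                f"\tlength={c.length}\tstate{state},cn={c.cn}"
                f"\t{c.sample_id}\tstartsnp=NA\tendsnp=NA{conf}\n"
            )


#: default column names of a GenomeStudio CNVPartition export; remap via
#: the ``columns`` argument when a GenomeStudio version differs.
CNVPARTITION_COLUMNS = {
    "sample": "Sample ID",
    "chrom": "Chromosome",
    "start": "Start",
    "end": "End",
    "cn": "Value",
    "conf": "Confidence",
    "n_snp": "Num SNPs",
}


def read_cnvpartition_calls(
    path: str | Path,
    build: str = "",
    *,
    conf_floor: float = 35.0,
    columns: Optional[Dict[str, str]] = None,
    keep_sex_chroms: bool = False,
) -> List[CnvCall]:
    """Parse a CNVPartition CNV export table.

    Rows with confidence below ``conf_floor`` (caller default 35) are
    excluded, matching the threshold CNVPartition itself is usually run
    with.  A missing required column raises :class:`SchemaError`.
    """
    cols = dict(CNVPARTITION_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [cols[k] for k in ("sample", "chrom", "start", "end", "cn")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    has_conf = cols["conf"] in df.columns
    has_nsnp = cols["n_snp"] in df.columns
    calls: List[CnvCall] = []
    for idx, row in df.iterrows():
        chrom = _norm_chrom(row[cols["chrom"]])
        if not keep_sex_chroms and chrom in SEX_CHROMS:
            continue
        cn = int(float(row[cols["cn"]]))
        if cn not in VALID_CN:
            log.warning("%s: row %d: rejected record with cn=%d", path, idx, cn)
            continue
        conf = float(row[cols["conf"]]) if has_conf and pd.notna(row[cols["conf"]]) else None
        if conf is not None and conf < conf_floor:
            continue
        calls.append(
            CnvCall(
                sample_id=str(row[cols["sample"]]),
                chrom=chrom,
                start=int(float(row[cols["start"]])),
                end=int(float(row[cols["end"]])),
                cn=cn,
                n_snp=int(float(row[cols["n_snp"]])) if has_nsnp else 1,
                conf=conf,
                caller=CNVPARTITION,
                build=build,
            )
        )
    if df.empty:
        log.warning("%s: empty CNVPartition export", path)
    return calls


def write_cnvpartition_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    cols = CNVPARTITION_COLUMNS
    rows = [
        {
            cols["sample"]: c.sample_id,
            cols["chrom"]: c.chrom,
            cols["start"]: c.start,
            cols["end"]: c.end,
            cols["cn"]: c.cn,
            cols["conf"]: "" if c.conf is None else f"{c.conf:.3f}",
            cols["n_snp"]: c.n_snp,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, sep="\t", index=False)


def read_snp_map(
    path: str | Path,
    *,
    unknown_chroms: Sequence[str] = UNKNOWN_CHROMS,
) -> List[SnpMarker]:
    """Read a three-column SNP map (name, chromosome, position; TSV or CSV).

    A header row is detected automatically.  Chromosome ``0``/``NA``/``Un*``
    or position <= 0 marks the marker as unmapped.  Duplicate marker names
    raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     skip_blank_lines=True, comment="#")
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: expected 3 columns, found {df.shape[1]}")
    df = df.iloc[:, :3]
    first_pos = str(df.iloc[0, 2]).strip()
    try:
        float(first_pos)
    except ValueError:
        df = df.iloc[1:]  # header row
    markers: List[SnpMarker] = []
    for name, chrom, pos in df.itertuples(index=False):
        name = str(name).strip()
        chrom = "" if pd.isna(chrom) else _norm_chrom(chrom)
        try:
            pos_i = int(float(pos))
        except (TypeError, ValueError):
            pos_i = 0
        unmapped = chrom in unknown_chroms or chrom.startswith("Un") or pos_i <= 0
        if unmapped:
            markers.append(SnpMarker(name))
        else:
            markers.append(SnpMarker(name, chrom, pos_i))
    names = [m.name for m in markers]
    if len(set(names)) != len(names):
        seen, dups = set(), []
        for n in names:
            if n in seen:
                dups.append(n)
            seen.add(n)
        raise SchemaError(f"{path}: duplicate marker names: {sorted(set(dups))[:10]}")
    return markers


def write_snp_map(markers: Iterable[SnpMarker], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Name\tChromosome\tPosition\n")
        for m in markers:
            if m.is_mapped:
                fh.write(f"{m.name}\t{m.chrom}\t{m.pos}\n")
            else:
                fh.write(f"{m.name}\t0\t0\n")


@dataclass(frozen=True)
class RefGeneColumns:
    """0-based column indices of a refGene-style table (UCSC dump layout)."""

    chrom: int = 2
    strand: int = 3
    tx_start: int = 4
    tx_end: int = 5
    gene_name: int = 12
    zero_based_start: bool = True


def read_refgene(
    path: str | Path,
    *,
    columns: RefGeneColumns = RefGeneColumns(),
    keep_sex_chroms: bool = False,
) -> List[GeneRecord]:
    """Read a refGene-format annotation table into gene-level records.

    Multiple transcript rows of one gene on one chromosome are collapsed to
    the union interval.  Rows with tx_start >= tx_end are rejected with a
    warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        log.warning("%s: empty annotation file", path)
        return []
    need = max(columns.chrom, columns.strand, columns.tx_start,
               columns.tx_end, columns.gene_name)
    if df.shape[1] <= need:
        raise SchemaError(
            f"{path}: refGene table has {df.shape[1]} columns, "
            f"need index {need}"
        )
    spans: Dict[Tuple[str, str], List[int]] = {}
    strands: Dict[Tuple[str, str], str] = {}
    for idx, row in df.iterrows():
        chrom = _norm_chrom(row[columns.chrom])
        if not keep_sex_chroms and chrom in SEX_CHROMS:
            continue
        s = int(row[columns.tx_start]) + (1 if columns.zero_based_start else 0)
        e = int(row[columns.tx_end])
        if s >= e:
            log.warning("%s: row %d: rejected gene row with tx_start >= tx_end", path, idx)
            continue
        key = (str(row[columns.gene_name]), chrom)
        if key in spans:
            spans[key][0] = min(spans[key][0], s)
            spans[key][1] = max(spans[key][1], e)
        else:
            spans[key] = [s, e]
            strands[key] = str(row[columns.strand])
    genes = [
        GeneRecord(gene_name=g, chrom=c, tx_start=se[0], tx_end=se[1], strand=strands[(g, c)])
        for (g, c), se in spans.items()
    ]
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.tx_start, g.gene_name))
    return genes


def write_refgene(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes in refGene layout (one transcript row per gene)."""
    with open(path, "w") as fh:
        for i, g in enumerate(genes):
            tx_start0 = g.tx_start - 1
            fh.write(
                "\t".join(
                    [
                        "0",                      # bin
                        f"TX_{i:06d}",            # transcript id
                        g.chrom,
                        g.strand,
                        str(tx_start0),
                        str(g.tx_end),
                        str(tx_start0),           # cdsStart
                        str(g.tx_end),            # cdsEnd
                        "1",                      # exonCount
                        f"{tx_start0},",
                        f"{g.tx_end},",
                        "0",                      # score
                        g.gene_name,              # name2
                        "none", "none", "-1,",
                    ]
                )
                + "\n"
            )


def read_sample_qc(path: str | Path) -> List[SampleQcRecord]:
    """Read a per-sample QC table (sample_id, lrr_sd, baf_drift, wave_factor)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "lrr_sd", "baf_drift", "wave_factor"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing QC columns {missing}")
    return [
        SampleQcRecord(str(r.sample_id), float(r.lrr_sd), float(r.baf_drift),
                       float(r.wave_factor))
        for r in df.itertuples(index=False)
    ]


def write_sample_qc(records: Iterable[SampleQcRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlrr_sd\tbaf_drift\twave_factor\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.lrr_sd:.4f}\t{r.baf_drift:.5f}\t{r.wave_factor:.4f}\n")


def read_genome(path: str | Path, name: str = "genome") -> GenomeBuild:
    """Read a two-column chromosome-length TSV into a :class:`GenomeBuild`."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    try:
        int(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    lengths = {_norm_chrom(c): int(n) for c, n in df.iloc[:, :2].itertuples(index=False)}
    return GenomeBuild(name=name, chrom_lengths=lengths, n_autosomes=len(lengths))


def write_genome(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(genome.chrom_lengths, key=chrom_sort_key):
            fh.write(f"{c}\t{genome.chrom_lengths[c]}\n")


def write_cnvr_bed(
    regions: Sequence[CnvRegion],
    bed_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Write CNV regions as BED6 (0-based half-open) plus a full TSV sidecar.

    BED columns: chrom, start-1, end, region id, n_samples, type.  The TSV
    sidecar keeps every region field so a read-back reconstructs the
    regions exactly.
    """
    regions = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end))
    bed_path = Path(bed_path)
    if tsv_path is None:
        tsv_path = bed_path.with_suffix(".tsv")
    with open(bed_path, "w") as fh:
        fh.write("# chrom\tstart\tend\tregion_id\tn_samples\ttype\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}"
                     f"\t{r.n_samples}\t{r.type}\n")
    with open(tsv_path, "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\ttype\tn_samples\tn_calls\tlength\tsource\n")
        for r in regions:
            fh.write(f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.type}"
                     f"\t{r.n_samples}\t{r.n_calls}\t{r.length}\t{r.source}\n")


def read_cnvr_tsv(path: str | Path) -> List[CnvRegion]:
    """Read back a region TSV sidecar (member calls are not reconstructed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["region_id", "chrom", "start", "end", "type", "n_samples", "n_calls"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing region columns {missing}")
    return [
        CnvRegion(
            region_id=str(r.region_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            type=str(r.type),
            n_samples=int(r.n_samples),
            n_calls=int(r.n_calls),
            source="" if pd.isna(getattr(r, "source", "")) else str(getattr(r, "source", "")),
        )
        for r in df.itertuples(index=False)
    ]
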