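"""Synthetic SNP-array CNV cohorts with known ground truth.

The generator emulates the structure of a cattle genotyping cohort: a few
hundred samples over 29 autosomes, planted CNV regions (archetypes) of
gain/loss/mixed type with copy-number states 0/1/3/4 and per-sample
penetrance, two caller outputs (PennCNV-format and CNVPartition-format)
observing the same true events, per-sample signal-QC records, paired SNP
maps with planted cross-assembly discrepancies, and gene intervals placed
inside and outside the planted regions.  A :class:`TruthManifest` records
everything that was planted so each pipeline stage can be scored against
ground truth.

Given the same :class:`SimConfig` (including the seed), the output files
are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import io as ckio
from .types import (
    CNVPARTITION,
    GAIN,
    LOSS,
    MIXED,
    PENNCNV,
    CnvCall,
    ConfigError,
    GeneRecord,
    GenomeBuild,
    SampleQcRecord,
    SnpMarker,
)

CALLERS = (PENNCNV, CNVPARTITION)


@dataclass(frozen=True)
class CnvrArchetype:
    """One planted CNV region: locus, type, carrier frequency, CN states."""

    chrom: str
    start: int
    end: int
    kind: str  # gain | loss | mixed
    frequency: float
    #: per-state probabilities; defaults reflect that one- and three-copy
    #: events dominate SNP-array calls while zero- and four-copy are rare
    cn_probs: Optional[Tuple[Tuple[int, float], ...]] = None

    def states(self) -> Tuple[Tuple[int, float], ...]:
        if self.cn_probs is not None:
            return self.cn_probs
        if self.kind == GAIN:
            return ((3, 0.9), (4, 0.1))
        if self.kind == LOSS:
            return ((1, 0.85), (0, 0.15))
        return ((1, 0.45), (0, 0.05), (3, 0.45), (4, 0.05))

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def default_archetypes() -> Tuple[CnvrArchetype, ...]:
    """Eight planted regions spanning the frequency range of interest.

    Frequencies bracket the 5% consensus proportion: well above (0.30,
    0.25, 0.15), at (0.08, 0.05), and below (0.02, 0.01), across all three
    region types.
    """
    return (
        CnvrArchetype("1", 2_000_001, 2_400_000, LOSS, 0.30),
        CnvrArchetype("2", 5_000_001, 5_600_000, GAIN, 0.25),
        CnvrArchetype("3", 1_000_001, 1_800_000, MIXED, 0.15),
        CnvrArchetype("5", 3_000_001, 3_300_000, LOSS, 0.08),
        CnvrArchetype("8", 6_000_001, 6_500_000, GAIN, 0.05),
        CnvrArchetype("12", 4_000_001, 4_250_000, MIXED, 0.05),
        CnvrArchetype("15", 7_000_001, 7_200_000, LOSS, 0.02),
        CnvrArchetype("20", 1_500_001, 1_700_000, GAIN, 0.01),
    )


@dataclass(frozen=True)
class MapDiscrepancyRates:
    """Per-marker probabilities of each planted cross-assembly discrepancy.

    Defaults echo the magnitude seen when comparing an old and a new
    assembly of the same bovine array: ~10% of markers unplaced in the
    older map (A), well under 1% for every other category.
    """

    different_chromosomes: float = 0.002
    both_unknown: float = 0.002
    unknown_in_a: float = 0.10
    unknown_in_b: float = 0.004
    missing_from_a: float = 0.004
    missing_from_b: float = 0.001
    local_shuffle: float = 0.01   # probability a window of map B is reordered
    shuffle_window: int = 10

    def category_probs(self) -> Tuple[Tuple[str, float], ...]:
        return (
            ("different_chromosomes", self.different_chromosomes),
            ("both_unknown", self.both_unknown),
            ("unknown_in_a", self.unknown_in_a),
            ("unknown_in_b", self.unknown_in_b),
            ("missing_from_a", self.missing_from_a),
            ("missing_from_b", self.missing_from_b),
        )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Desk-scale defaults: 400 samples, 29 autosomes of 10 Mb, one marker
    every 2 kb (~145k markers, the scale of a 150K chip), planted regions
    from :func:`default_archetypes`, 2% breakpoint jitter, perfect caller
    detection, 0.5 false-positive calls per sample per caller, 2% of
    samples failing signal QC.
    """

    seed: int = 0
    n_autosomes: int = 29
    chrom_length_bp: int = 10_000_000
    n_samples: int = 400
    snp_spacing_bp: int = 2_000
    archetypes: Tuple[CnvrArchetype, ...] = field(default_factory=default_archetypes)
    breakpoint_jitter_frac: float = 0.02
    fp_call_rate: float = 0.5          # Poisson mean per sample per caller
    caller_detection_prob: Tuple[Tuple[str, float], ...] = (
        (PENNCNV, 1.0),
        (CNVPARTITION, 1.0),
    )
    qc_fail_frac: float = 0.02
    oversize_artifact_frac: float = 0.0  # samples carrying one >5 Mb artefact
    genes_per_archetype: int = 2
    n_background_genes: int = 50
    map_rates: MapDiscrepancyRates = field(default_factory=MapDiscrepancyRates)
    build_name: str = "simA"

    def __post_init__(self) -> None:
        probs = [self.breakpoint_jitter_frac, self.qc_fail_frac,
                 self.oversize_artifact_frac]
        probs += [p for _, p in self.caller_detection_prob]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must be in [0, 1]")
        if self.fp_call_rate < 0:
            raise ConfigError("fp_call_rate must be >= 0")
        cat_total = sum(p for _, p in self.map_rates.category_probs())
        if cat_total > 1.0:
            raise ConfigError("map discrepancy rates sum to more than 1")
        for a in self.archetypes:
            if not (0.0 < a.frequency <= 1.0):
                raise ConfigError(f"archetype frequency {a.frequency} not in (0, 1]")
            if int(a.chrom) > self.n_autosomes or a.end > self.chrom_length_bp:
                raise ConfigError(
                    f"archetype {a.chrom}:{a.start}-{a.end} exceeds the genome"
                )

    def detection_prob(self, caller: str) -> float:
        return dict(self.caller_detection_prob)[caller]

    @property
    def genome(self) -> GenomeBuild:
        return GenomeBuild(
            name=self.build_name,
            chrom_lengths={str(c): self.chrom_length_bp
                           for c in range(1, self.n_autosomes + 1)},
            n_autosomes=self.n_autosomes,
        )

    @property
    def sample_ids(self) -> Tuple[str, ...]:
        return tuple(f"S{i:04d}" for i in range(1, self.n_samples + 1))


@dataclass(frozen=True)
class PlantedRegion:
    """Ground truth for one archetype after carrier sampling."""

    index: int
    chrom: str
    start: int
    end: int
    kind: str
    target_frequency: float
    carriers: Tuple[str, ...]                       # samples with a true event
    carriers_by_caller: Mapping[str, Tuple[str, ...]]

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class TruthManifest:
    """Everything the simulator planted, for scoring pipeline output."""

    planted: Tuple[PlantedRegion, ...]
    map_categories: Mapping[str, str]     # marker name -> category
    shuffled_markers: Tuple[str, ...]     # same-chrom markers in reordered windows
    gene_archetype: Mapping[str, Optional[int]]  # gene -> planted region index
    qc_fail_samples: Tuple[str, ...]
    oversize_call_keys: Tuple[str, ...]

    def to_json(self) -> str:
        payload = {
            "planted": [
                {
                    "index": p.index,
                    "chrom": p.chrom,
                    "start": p.start,
                    "end": p.end,
                    "kind": p.kind,
                    "target_frequency": p.target_frequency,
                    "carriers": list(p.carriers),
                    "carriers_by_caller": {k: list(v) for k, v in
                                           p.carriers_by_caller.items()},
                }
                for p in self.planted
            ],
            "map_categories": dict(self.map_categories),
            "shuffled_markers": list(self.shuffled_markers),
            "gene_archetype": dict(self.gene_archetype),
            "qc_fail_samples": list(self.qc_fail_samples),
            "oversize_call_keys": list(self.oversize_call_keys),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimBundle:
    """In-memory view of one simulated cohort (plus file paths if written)."""

    config: SimConfig
    genome: GenomeBuild
    penncnv_calls: List[CnvCall]
    cnvpartition_calls: List[CnvCall]
    map_a: List[SnpMarker]
    map_b: List[SnpMarker]
    genes: List[GeneRecord]
    qc: List[SampleQcRecord]
    truth: TruthManifest
    paths: Dict[str, Path] = field(default_factory=dict)


def _jitter(rng: np.random.Generator, value: int, radius: int,
            low: int, high: int) -> int:
    if radius <= 0:
        return value
    return int(np.clip(value + rng.integers(-radius, radius + 1), low, high))


def _draw_cn(rng: np.random.Generator, states: Tuple[Tuple[int, float], ...]) -> int:
    cns = [cn for cn, _ in states]
    ps = np.array([p for _, p in states], dtype=float)
    ps = ps / ps.sum()
    return int(rng.choice(cns, p=ps))


def simulate_calls(
    cfg: SimConfig, rng: np.random.Generator
) -> Tuple[List[CnvCall], List[CnvCall], Tuple[PlantedRegion, ...], Tuple[str, ...]]:
    """Draw carriers and emit per-caller call lists plus planted-region truth."""
    samples = cfg.sample_ids
    calls: Dict[str, List[CnvCall]] = {c: [] for c in CALLERS}
    planted: List[PlantedRegion] = []
    L = cfg.chrom_length_bp

    for idx, arch in enumerate(cfg.archetypes):
        carrier_mask = rng.random(cfg.n_samples) < arch.frequency
        radius = int(cfg.breakpoint_jitter_frac * arch.span)
        carriers: List[str] = []
        by_caller: Dict[str, List[str]] = {c: [] for c in CALLERS}
        for s_i, sample in enumerate(samples):
            if not carrier_mask[s_i]:
                continue
            carriers.append(sample)
            start = _jitter(rng, arch.start, radius, 1, L - 1)
            end = _jitter(rng, arch.end, radius, start + 1, L)
            cn = _draw_cn(rng, arch.states())
            n_snp = max(3, round((end - start + 1) / cfg.snp_spacing_bp))
            for caller in CALLERS:
                detected = rng.random() < cfg.detection_prob(caller)
                conf = (round(float(rng.uniform(15, 100)), 3) if caller == PENNCNV
                        else round(float(rng.uniform(36, 99)), 3))
                if detected:
                    calls[caller].append(
                        CnvCall(sample, arch.chrom, start, end, cn, n_snp,
                                conf, caller, cfg.build_name)
                    )
                    by_caller[caller].append(sample)
        planted.append(
            PlantedRegion(
                index=idx,
                chrom=arch.chrom,
                start=arch.start,
                end=arch.end,
                kind=arch.kind,
                target_frequency=arch.frequency,
                carriers=tuple(carriers),
                carriers_by_caller={c: tuple(v) for c, v in by_caller.items()},
            )
        )

    # false-positive singleton calls, anywhere on the genome
    for caller in CALLERS:
        for sample in samples:
            for _ in range(int(rng.poisson(cfg.fp_call_rate))):
                chrom = str(int(rng.integers(1, cfg.n_autosomes + 1)))
                length = int(rng.integers(10_000, 50_001))
                start = int(rng.integers(1, L - length))
                cn = int(rng.choice([0, 1, 3, 4]))
                conf = round(float(rng.uniform(36, 99)), 3)
                calls[caller].append(
                    CnvCall(sample, chrom, start, start + length - 1, cn,
                            max(3, length // cfg.snp_spacing_bp), conf,
                            caller, cfg.build_name)
                )

    # oversize artefacts (> 5 Mb), planted in a fraction of samples
    oversize_keys: List[str] = []
    if cfg.oversize_artifact_frac > 0:
        mask = rng.random(cfg.n_samples) < cfg.oversize_artifact_frac
        for s_i, sample in enumerate(samples):
            if not mask[s_i]:
                continue
            chrom = str(int(rng.integers(1, cfg.n_autosomes + 1)))
            length = 6_000_000
            start = int(rng.integers(1, max(2, L - length)))
            cn = int(rng.choice([1, 3]))
            for caller in CALLERS:
                call = CnvCall(sample, chrom, start, start + length - 1, cn,
                               max(3, length // cfg.snp_spacing_bp),
                               50.0, caller, cfg.build_name)
                calls[caller].append(call)
                oversize_keys.append(call.key)

    for caller in CALLERS:
        calls[caller].sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return (calls[PENNCNV], calls[CNVPARTITION], tuple(planted),
            tuple(oversize_keys))


def simulate_qc(
    cfg: SimConfig, rng: np.random.Generator
) -> Tuple[List[SampleQcRecord], Tuple[str, ...]]:
    """Per-sample QC statistics with a planted fraction of failing samples."""
    records: List[SampleQcRecord] = []
    fails: List[str] = []
    fail_mask = rng.random(cfg.n_samples) < cfg.qc_fail_frac
    for s_i, sample in enumerate(cfg.sample_ids):
        lrr = float(rng.uniform(0.05, 0.25))
        drift = float(rng.uniform(0.0, 0.004))
        wave = float(rng.uniform(-0.08, 0.08))
        if fail_mask[s_i]:
            which = int(rng.integers(0, 3))
            if which == 0:
                lrr = float(rng.uniform(0.31, 0.60))
            elif which == 1:
                drift = float(rng.uniform(0.006, 0.02))
            else:
                wave = float(rng.choice([-1, 1]) * rng.uniform(0.11, 0.30))
            fails.append(sample)
        records.append(SampleQcRecord(sample, round(lrr, 4), round(drift, 5),
                                      round(wave, 4)))
    return records, tuple(fails)


def simulate_genes(cfg: SimConfig) -> Tuple[List[GeneRecord], Dict[str, Optional[int]]]:
    """Genes planted inside each archetype plus background genes outside all.

    Deterministic given the config (no random draws needed): inside genes
    subdivide the archetype span; background genes sit in the top 1.5 Mb of
    each chromosome, far above every default archetype.
    """
    genes: List[GeneRecord] = []
    placement: Dict[str, Optional[int]] = {}
    for idx, arch in enumerate(cfg.archetypes):
        k = cfg.genes_per_archetype
        step = arch.span // (k + 1)
        glen = max(2_000, step // 2)
        for j in range(k):
            start = arch.start + (j + 1) * step - glen // 2
            end = min(start + glen - 1, arch.end)
            name = f"GENE_A{idx}_{j}"
            genes.append(GeneRecord(name, arch.chrom, start, end,
                                    "+" if j % 2 == 0 else "-"))
            placement[name] = idx
    arch_ivs: Dict[str, List[Tuple[int, int]]] = {}
    for a in cfg.archetypes:
        arch_ivs.setdefault(a.chrom, []).append((a.start, a.end))
    for k in range(cfg.n_background_genes):
        chrom = str(k % cfg.n_autosomes + 1)
        start = cfg.chrom_length_bp - 1_500_000 + (k // cfg.n_autosomes) * 60_000 + 1
        end = start + 20_000 - 1
        if any(not (end < s or start > e) for s, e in arch_ivs.get(chrom, ())):
            continue  # would touch a planted region; skip rather than mislabel
        name = f"GENE_BG{k:03d}"
        genes.append(GeneRecord(name, chrom, start, end, "+"))
        placement[name] = None
    genes.sort(key=lambda g: (int(g.chrom), g.tx_start))
    return genes, placement


def simulate_map_pair(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[SnpMarker], List[SnpMarker], Dict[str, str], Tuple[str, ...]]:
    """Paired SNP maps with planted discrepancies.

    Markers are laid on a regular grid in map A; each independently draws
    a discrepancy category for map B at the configured rates.  A fraction
    of same-chromosome windows additionally have their map-B positions
    permuted to plant order discordance.  Returns (map A, map B, category
    per marker, names of markers in shuffled windows).
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 7])
    rates = cfg.map_rates
    cats = rates.category_probs()
    edges = np.cumsum([p for _, p in cats])
    map_a: List[SnpMarker] = []
    map_b: List[SnpMarker] = []
    categories: Dict[str, str] = {}
    shuffled: List[str] = []
    n_per_chrom = cfg.chrom_length_bp // cfg.snp_spacing_bp
    for chrom_i in range(1, cfg.n_autosomes + 1):
        chrom = str(chrom_i)
        u = rng.random(n_per_chrom)
        b_entries: List[Tuple[str, Optional[str], Optional[int]]] = []
        for i in range(n_per_chrom):
            name = f"SNP{chrom_i}_{i + 1:05d}"
            pos = (i + 1) * cfg.snp_spacing_bp
            j = int(np.searchsorted(edges, u[i], side="right"))
            cat = cats[j][0] if j < len(cats) else "same_chromosome"
            categories[name] = cat
            if cat != "missing_from_a":
                if cat in ("unknown_in_a", "both_unknown"):
                    map_a.append(SnpMarker(name))
                else:
                    map_a.append(SnpMarker(name, chrom, pos))
            if cat == "missing_from_b":
                continue
            if cat in ("unknown_in_b", "both_unknown"):
                b_entries.append((name, None, None))
            elif cat == "different_chromosomes":
                other = int(rng.integers(1, cfg.n_autosomes + 1))
                if other == chrom_i:
                    other = other % cfg.n_autosomes + 1
                b_entries.append((name, str(other),
                                  int(rng.integers(1, cfg.chrom_length_bp + 1))))
            else:
                b_entries.append((name, chrom, pos))
        # plant order discordance: permute positions inside random windows of
        # consecutive same-chromosome markers
        same_idx = [k for k, (_, c, _) in enumerate(b_entries) if c == chrom]
        w = rates.shuffle_window
        for block_start in range(0, len(same_idx) - w + 1, w):
            if rng.random() >= rates.local_shuffle:
                continue
            block = same_idx[block_start : block_start + w]
            pos_block = [b_entries[k][2] for k in block]
            perm = rng.permutation(w)
            for slot, k in enumerate(block):
                name, c, _ = b_entries[k]
                b_entries[k] = (name, c, pos_block[int(perm[slot])])
                shuffled.append(name)
        for name, c, p in b_entries:
            map_b.append(SnpMarker(name) if c is None else SnpMarker(name, c, p))
    return map_a, map_b, categories, tuple(shuffled)


def simulate_cohort(cfg: SimConfig, out_dir: str | Path | None = None) -> SimBundle:
    """Generate a full synthetic cohort; optionally write all input files.

    Written files (when ``out_dir`` is given): ``penncnv.rawcnv``,
    ``cnvpartition.tsv``, ``map_A.tsv``, ``map_B.tsv``, ``refgene.txt``,
    ``sample_qc.tsv``, ``genome.tsv`` and ``truth.json``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    penn, part, planted, oversize = simulate_calls(cfg, rng)
    qc, qc_fails = simulate_qc(cfg, rng)
    genes, gene_truth = simulate_genes(cfg)
    map_a, map_b, categories, shuffled = simulate_map_pair(cfg)
    truth = TruthManifest(
        planted=planted,
        map_categories=categories,
        shuffled_markers=shuffled,
        gene_archetype=gene_truth,
        qc_fail_samples=qc_fails,
        oversize_call_keys=oversize,
    )
    bundle = SimBundle(
        config=cfg,
        genome=cfg.genome,
        penncnv_calls=penn,
        cnvpartition_calls=part,
        map_a=map_a,
        map_b=map_b,
        genes=genes,
        qc=qc,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "penncnv": out / "penncnv.rawcnv",
            "cnvpartition": out / "cnvpartition.tsv",
            "map_a": out / "map_A.tsv",
            "map_b": out / "map_B.tsv",
            "refgene": out / "refgene.txt",
            "qc": out / "sample_qc.tsv",
            "genome": out / "genome.tsv",
            "truth": out / "truth.json",
        }
        ckio.write_penncnv_calls(penn, paths["penncnv"])
        ckio.write_cnvpartition_calls(part, paths["cnvpartition"])
        ckio.write_snp_map(map_a, paths["map_a"])
        ckio.write_snp_map(map_b, paths["map_b"])
        ckio.write_refgene(genes, paths["refgene"])
        ckio.write_sample_qc(qc, paths["qc"])
        ckio.write_genome(cfg.genome, paths["genome"])
        paths["truth"].write_text(truth.to_json())
        bundle.paths = paths
    return bundle
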