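"""End-to-end driver: clean -> summarise -> regions -> compare -> consensus
-> genes -> map comparison, with TSV/BED/PNG outputs and a run manifest.

Every number written to a report table is recomputed from stage outputs;
the run manifest records inputs, parameters and package version so a rerun
on the same inputs reproduces identical tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as ckio
from .cleaning import CleanConfig, clean_calls, filter_samples_by_qc, summarize_cnvs
from .cnvr import call_cnvr, cnvr_summary
from .compare import (
    compare_cnv_individual,
    compare_cnv_population,
    compare_cnvr,
    compare_to_database,
    consensus_cnvrs,
    consensus_threshold,
)
from .genes import annotate_genes, consensus_genes
from .mapdiff import classify_marker_pairs, position_concordance, snp_density
from .types import CnvError, GenomeBuild

log = logging.getLogger(__name__)


class StageError(CnvError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run on one genome build."""

    out_dir: str
    genome_path: str
    penncnv_path: Optional[str] = None
    cnvpartition_path: Optional[str] = None
    qc_path: Optional[str] = None
    refgene_path: Optional[str] = None
    map_a_path: Optional[str] = None
    map_b_path: Optional[str] = None
    external_cnvr_path: Optional[str] = None  # database-style TSV of regions
    blacklist_path: Optional[str] = None      # BED-like TSV chrom,start,end,id
    clean: CleanConfig = field(default_factory=CleanConfig)
    consensus_proportion: float = 0.05
    cnvpartition_conf_floor: float = 35.0
    build_name: str = "A"
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        clean_raw = raw.pop("clean", {})
        return cls(clean=CleanConfig(**clean_raw), **raw)


@dataclass
class PipelineResult:
    """Everything the run produced, in memory plus written file paths."""

    summaries: Dict[str, object] = field(default_factory=dict)
    regions: Dict[str, list] = field(default_factory=dict)
    region_summaries: Dict[str, object] = field(default_factory=dict)
    cnv_compare: Dict[str, object] = field(default_factory=dict)
    cnvr_compare: Optional[object] = None
    consensus: Optional[object] = None
    threshold_n: Optional[int] = None
    gene_hits: list = field(default_factory=list)
    consensus_gene_hits: list = field(default_factory=list)
    map_comparison: Optional[object] = None
    concordance: Optional[object] = None
    db_compare: Optional[object] = None
    outputs: Dict[str, str] = field(default_factory=dict)
    log_lines: List[str] = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _write_rows(rows: Sequence[dict], path: Path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage the supplied inputs allow and write all outputs.

    Stages needing an absent input are skipped with a log note (e.g. with a
    single caller there is no cross-caller comparison and no consensus
    set).  Any stage failure aborts with a :class:`StageError` naming the
    stage; outputs written so far stay on disk and the manifest marks the
    run incomplete.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()
    note = res.log_lines.append
    manifest: Dict[str, object] = {
        "version": __version__,
        "config": {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "complete": False,
    }

    def save_manifest() -> None:
        manifest["outputs"] = res.outputs
        manifest["log"] = res.log_lines
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    try:
        genome = _stage("read-genome")(ckio.read_genome)(cfg.genome_path, cfg.build_name)

        # --- read and clean calls per caller -------------------------------
        kept_samples = None
        n_cohort = None
        if cfg.qc_path:
            qc = _stage("read-qc")(ckio.read_sample_qc)(cfg.qc_path)
            kept_samples, excluded = _stage("sample-qc")(filter_samples_by_qc)(qc, cfg.clean)
            n_cohort = len(kept_samples)
            _write_rows(
                [{"sample_id": s, "reasons": ",".join(r)} for s, r in excluded.items()],
                out / "excluded_samples.tsv",
            )
            res.outputs["excluded_samples"] = str(out / "excluded_samples.tsv")
            note(f"sample QC: kept {len(kept_samples)}, excluded {len(excluded)}")

        raw = {}
        if cfg.penncnv_path:
            raw["penncnv"] = _stage("read-penncnv")(ckio.read_penncnv_calls)(
                cfg.penncnv_path, cfg.build_name)
        if cfg.cnvpartition_path:
            raw["cnvpartition"] = _stage("read-cnvpartition")(ckio.read_cnvpartition_calls)(
                cfg.cnvpartition_path, cfg.build_name,
                conf_floor=cfg.cnvpartition_conf_floor)
        if not raw:
            raise StageError("stage 'read-calls' failed: no caller input given")

        cleaned: Dict[str, list] = {}
        for caller, calls in raw.items():
            kept, dropped = _stage("clean")(clean_calls)(
                calls, cfg.clean, kept_samples=kept_samples,
                merge=(caller == "penncnv"))  # gap-merge applies to PennCNV output
            cleaned[caller] = kept
            note(f"{caller}: {len(calls)} raw -> {len(kept)} cleaned "
                 f"({len(dropped)} over-length dropped)")
            n_ind = n_cohort if n_cohort else len({c.sample_id for c in kept}) or 1
            summary = summarize_cnvs(kept, n_ind) if kept else None
            res.summaries[caller] = summary
            if summary:
                _write_rows(summary.to_rows(), out / f"cnv_summary_{caller}.tsv")
                res.outputs[f"cnv_summary_{caller}"] = str(out / f"cnv_summary_{caller}.tsv")

        # --- regions per caller -------------------------------------------
        for caller, calls in cleaned.items():
            regions = _stage("call-cnvr")(call_cnvr)(calls, source=caller, genome=genome)
            res.regions[caller] = regions
            res.region_summaries[caller] = cnvr_summary(regions, genome) if regions else None
            ckio.write_cnvr_bed(regions, out / f"cnvr_{caller}.bed")
            res.outputs[f"cnvr_{caller}"] = str(out / f"cnvr_{caller}.bed")
            if res.region_summaries[caller]:
                _write_rows(res.region_summaries[caller].to_rows(),
                            out / f"cnvr_summary_{caller}.tsv")

        # --- cross-caller comparison and consensus ------------------------
        if len(cleaned) == 2:
            a, b = cleaned["penncnv"], cleaned["cnvpartition"]
            res.cnv_compare["individual"] = compare_cnv_individual(a, b)
            res.cnv_compare["population"] = compare_cnv_population(a, b)
            pairs, res.cnvr_compare = compare_cnvr(
                res.regions["penncnv"], res.regions["cnvpartition"])
            # "sample size" = individuals analysed per result: the QC-kept
            # cohort when known, else the samples present in each call list
            if n_cohort:
                sizes = [n_cohort]
            else:
                sizes = [len({c.sample_id for c in lst}) for lst in (a, b)]
            res.threshold_n = consensus_threshold(sizes, cfg.consensus_proportion)
            res.consensus = _stage("consensus")(consensus_cnvrs)(
                [a, b], res.threshold_n)
            ckio.write_cnvr_bed(list(res.consensus.union_regions), out / "cnvr_union.bed")
            ckio.write_cnvr_bed(list(res.consensus.regions), out / "cnvr_consensus.bed")
            res.outputs["cnvr_consensus"] = str(out / "cnvr_consensus.bed")
            note(f"consensus: threshold n>={res.threshold_n}, "
                 f"{len(res.consensus.regions)} of {len(res.consensus.union_regions)} "
                 "union regions kept")
        else:
            note("single caller input: cross-caller comparison and consensus skipped")

        # --- gene annotation ----------------------------------------------
        if cfg.refgene_path:
            genes = _stage("read-refgene")(ckio.read_refgene)(cfg.refgene_path)
            items = (list(res.consensus.union_regions)
                     if res.consensus is not None
                     else next(iter(res.regions.values())))
            cohort = n_cohort or len({c.sample_id
                                      for lst in cleaned.values() for c in lst})
            res.gene_hits = _stage("annotate")(annotate_genes)(
                items, genes, cohort_size=cohort)
            if res.threshold_n is not None:
                res.consensus_gene_hits = consensus_genes(res.gene_hits, res.threshold_n)
            _write_rows(
                [
                    {
                        "gene": h.gene_name, "chrom": h.chrom, "n_cnvs": h.n_cnvs,
                        "n_samples": h.n_samples,
                        "frequency_pct": "" if h.frequency_pct is None
                        else round(h.frequency_pct, 2),
                        "regions": ",".join(h.item_ids),
                    }
                    for h in res.gene_hits
                ],
                out / "gene_hits.tsv",
            )
            res.outputs["gene_hits"] = str(out / "gene_hits.tsv")
            note(f"annotation: {len(res.gene_hits)} genes hit, "
                 f"{len(res.consensus_gene_hits)} consensus genes")

        # --- cross-assembly map comparison --------------------------------
        if cfg.map_a_path and cfg.map_b_path:
            map_a = _stage("read-map")(ckio.read_snp_map)(cfg.map_a_path)
            map_b = _stage("read-map")(ckio.read_snp_map)(cfg.map_b_path)
            res.map_comparison = _stage("map-compare")(classify_marker_pairs)(map_a, map_b)
            res.concordance = position_concordance(map_a, map_b)
            _write_rows(res.map_comparison.to_rows(), out / "map_comparison.tsv")
            res.outputs["map_comparison"] = str(out / "map_comparison.tsv")
            dens = snp_density(map_b, genome) if genome else snp_density(map_b)
            _write_rows(
                [{"chrom": c, "snps_per_mb": round(d, 2)} for c, d in dens.items()],
                out / "snp_density_map_b.tsv",
            )

        # --- external database cross-validation ---------------------------
        if cfg.external_cnvr_path and res.regions:
            study = (list(res.consensus.union_regions) if res.consensus is not None
                     else next(iter(res.regions.values())))
            external = _stage("read-external")(ckio.read_cnvr_tsv)(cfg.external_cnvr_path)
            res.db_compare = compare_to_database(study, external)
            note(f"database comparison: {res.db_compare.n_study_hit}/"
                 f"{res.db_compare.n_study} study regions validated")

        # --- plots ---------------------------------------------------------
        if cfg.make_plots:
            from .plots import plot_position_concordance, render_cnvr_map

            all_regions = [r for lst in res.regions.values() for r in lst]
            if all_regions:
                p = render_cnvr_map(
                    all_regions, genome, out / "cnvr_map.png",
                    consensus=list(res.consensus.regions) if res.consensus else (),
                )
                res.outputs["cnvr_map"] = str(p)
            if res.concordance is not None:
                p = plot_position_concordance(res.concordance, out / "snp_order.png")
                res.outputs["snp_order"] = str(p)

        manifest["complete"] = True
    finally:
        save_manifest()
    return res
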