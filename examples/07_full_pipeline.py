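"""Run the whole pipeline from files on disk, the way a real analysis runs.

Simulates a cohort to disk, builds a PipelineConfig pointing at the files,
and executes clean -> summarise -> CNVRs -> cross-caller comparison ->
consensus -> gene annotation -> map comparison, writing TSV/BED/PNG
outputs and a MANIFEST.json.
"""
from pathlib import Path

from cnvrkit import PipelineConfig, SimConfig, run_pipeline, simulate_cohort

out = Path("scratch/example_pipeline")
bundle = simulate_cohort(SimConfig(seed=42), out / "inputs")

cfg = PipelineConfig(
    out_dir=str(out / "results"),
    genome_path=str(bundle.paths["genome"]),
    penncnv_path=str(bundle.paths["penncnv"]),
    cnvpartition_path=str(bundle.paths["cnvpartition"]),
    qc_path=str(bundle.paths["qc"]),
    refgene_path=str(bundle.paths["refgene"]),
    map_a_path=str(bundle.paths["map_a"]),
    map_b_path=str(bundle.paths["map_b"]),
)
res = run_pipeline(cfg)

print("run log:")
for line in res.log_lines:
    print(f"  {line}")
print(f"\n{len(res.consensus.regions)} consensus CNVRs at threshold "
      f">= {res.threshold_n} carriers")
print(f"{len(res.consensus_gene_hits)} consensus genes")
print(f"outputs written to {cfg.out_dir}/ (tables as TSV, regions as "
      "BED + TSV, figures as PNG, MANIFEST.json describing the run)")
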