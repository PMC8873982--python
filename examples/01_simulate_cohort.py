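"""Generate a synthetic SNP-array CNV cohort with a full truth manifest.

Writes PennCNV- and CNVPartition-format call files, paired SNP maps, a
refGene-style gene table, per-sample QC records and a truth.json, then
prints what was planted.
"""
from cnvrkit import SimConfig, simulate_cohort

cfg = SimConfig(seed=42)  # 400 samples, 29 x 10-Mb autosomes, 8 planted regions
bundle = simulate_cohort(cfg, out_dir="scratch/example_cohort")

print(f"wrote {len(bundle.paths)} files to scratch/example_cohort/")
print(f"{len(bundle.penncnv_calls)} PennCNV-style calls, "
      f"{len(bundle.cnvpartition_calls)} CNVPartition-style calls")
for p in bundle.truth.planted:
    print(f"  planted {p.kind:5s} region {p.chrom}:{p.start}-{p.end} "
          f"target freq {p.target_frequency:.2f} -> {p.n_carriers} carriers")
# Carrier counts are binomial draws at the target frequency; regions with
# >= 20 carriers (5% of 400) should later survive consensus calling.
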