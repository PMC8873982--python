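"""Merge per-sample CNV calls into population CNV regions (CNVRs).

Calls sharing >= 1 bp merge into one region; each region is classified as
gain (all members duplicated), loss (all deleted) or mixed.  Prints the
per-type region counts, total length and genome coverage.
"""
from cnvrkit import SimConfig, call_cnvr, cnvr_summary, simulate_cohort

bundle = simulate_cohort(SimConfig(seed=42))
regions = call_cnvr(bundle.penncnv_calls, source="penncnv", genome=bundle.genome)
summary = cnvr_summary(regions, bundle.genome)

print(f"{len(bundle.penncnv_calls)} calls -> {summary.total_count} CNVRs")
for row in summary.to_rows():
    print(f"  {row['type']:5s}: n={row['n_regions']:4} "
          f"total {row['total_length']:,} bp")
print(f"genome coverage: {summary.genome_coverage_pct:.2f}% "
      f"of {bundle.genome.total_length / 1e9:.2f} Gb")
top = max(regions, key=lambda r: r.n_samples)
print(f"most frequent region: {top.region_id} {top.chrom}:{top.start}-{top.end} "
      f"({top.type}, {top.n_samples} carriers)")
# The carrier count (distinct samples) is the frequency used later for
# consensus thresholds; singleton regions are mostly false-positive calls.
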