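"""Call consensus CNVRs from the pooled caller outputs and find consensus
genes.

The threshold is 5% of the smallest per-caller cohort, rounded up; a
region (or gene) passes when that many distinct samples carry it.
"""
from cnvrkit import (
    SimConfig,
    annotate_genes,
    consensus_cnvrs,
    consensus_genes,
    consensus_threshold,
    simulate_cohort,
)

cfg = SimConfig(seed=42)
bundle = simulate_cohort(cfg)
penn, part = bundle.penncnv_calls, bundle.cnvpartition_calls

thr = consensus_threshold([cfg.n_samples], proportion=0.05)
print(f"cohort of {cfg.n_samples} -> consensus threshold: >= {thr} carriers")

cs = consensus_cnvrs([penn, part], thr)
print(f"union set: {len(cs.union_regions)} CNVRs; "
      f"{len(cs.regions)} pass the threshold:")
for r in cs.regions:
    print(f"  {r.region_id} {r.chrom}:{r.start}-{r.end} "
          f"{r.type:5s} carriers={r.n_samples}")

hits = annotate_genes(list(cs.union_regions), bundle.genes,
                      cohort_size=cfg.n_samples)
keep = consensus_genes(hits, thr)
print(f"\n{len(hits)} genes intersect a union CNVR; "
      f"{len(keep)} are consensus genes (>= {thr} carriers):")
for h in keep[:8]:
    print(f"  {h.gene_name:12s} chr{h.chrom}: {h.n_samples} carriers "
          f"({h.frequency_pct:.1f}%)")
# Consensus genes sit inside the high-frequency planted regions; genes in
# low-frequency or false-positive regions fall below the threshold.
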