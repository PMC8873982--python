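# cnvrkit

Post-calling copy-number-variant (CNV) analysis for SNP-array cohorts.

SNP-array CNV studies (common in livestock genomics, where cohorts of a few
hundred animals are genotyped on ~150K bead chips) infer per-sample CNV
segments with callers such as PennCNV and GenomeStudio's CNVPartition.
Everything after that — cleaning the calls, turning them into
population-level CNV regions (CNVRs), reconciling two callers and two
genome assemblies, and deciding which regions and genes are trustworthy —
is the part this package implements, as a tested Python library.

## What it does

* **Parse** PennCNV `rawcnv` output, CNVPartition/GenomeStudio CNV exports,
  three-column SNP map files, refGene-style gene tables and per-sample
  signal-QC records.
* **Clean** calls: exclude samples with LRR SD > 0.30, BAF drift > 0.005 or
  |wave factor| > 0.1; merge adjacent same-state calls whose gap is < 20%
  of the merged span; drop calls longer than 5 Mb (all configurable).
* **Build CNVRs**: merge calls sharing ≥ 1 bp into regions, classify each
  as gain / loss / mixed, and report distinct-sample carrier frequencies,
  per-type length statistics and genome coverage.
* **Compare**: caller-vs-caller CNV overlap at the individual and the
  population level; CNVR-vs-CNVR overlap with union-based length
  accounting; cross-validation against external (e.g. DGVa-style) CNVR
  compilations; blacklist flagging of known assembly-error regions.
* **Consensus calling**: pool both callers, keep regions carried by at
  least `ceil(0.05 × min cohort size)` distinct samples; same rule for
  consensus genes, which are then compared across genome assemblies by
  name.
* **Compare SNP manifests** of one chip across two assemblies: a
  seven-category partition of every marker (same chromosome, moved,
  unplaced, missing), per-chromosome SNP density, and exact
  discordant-pair counts of marker order.
* **Simulate** full synthetic cohorts with a ground-truth manifest —
  planted CNVRs with chosen frequencies and types, breakpoint jitter,
  false-positive calls, QC failures, paired maps with planted
  discrepancies — so the whole pipeline is testable end to end.

The core statistic throughout is the **carrier frequency** of a region or
gene: the number of distinct samples whose calls intersect it. A CNVR is a
connected component of the ≥1-bp-overlap graph of calls; a consensus CNVR
is a region of the pooled two-caller union set with carrier count
`n ≥ ⌈0.05 · N_min⌉`, where `N_min` is the smallest per-result cohort
size (e.g. `⌈393 × 0.05⌉ = 20`).

## Worked example

```python
from cnvrkit import (SimConfig, simulate_cohort, consensus_threshold,
                     consensus_cnvrs)

cfg = SimConfig(seed=42)                      # 400 samples, 29 autosomes
bundle = simulate_cohort(cfg)
thr = consensus_threshold([cfg.n_samples], 0.05)
cs = consensus_cnvrs([bundle.penncnv_calls, bundle.cnvpartition_calls], thr)
print(f"threshold >= {thr} carriers: "
      f"{len(cs.regions)} consensus of {len(cs.union_regions)} union CNVRs")
for r in cs.regions:
    print(r.region_id, f"{r.chrom}:{r.start}-{r.end}", r.type, r.n_samples)
```

prints

```
threshold >= 20 carriers: 5 consensus of 388 union CNVRs
CNVR_3 1:1992194-2407978 mixed 122
CNVR_22 2:4988212-5611780 gain 106
CNVR_32 3:985821-1814161 mixed 63
CNVR_68 5:2994029-3344712 mixed 35
CNVR_156 12:3995061-4254902 mixed 22
```

i.e. of the 388 regions in the pooled union set, exactly the five planted
at carrier frequencies above 5% survive the threshold; each region spans
the planted locus (jittered breakpoints widen it slightly), and the
carrier counts are the realized binomial draws at the planted
frequencies. Two planted loss regions surface as *mixed* because random
false-positive duplication calls landed inside them — exactly the
behaviour that makes frequency thresholds necessary on real data.

The `examples/` directory walks through each capability (simulation,
cleaning, CNVR calling, caller comparison, consensus + genes, map
comparison, the full file-based pipeline); each script prints the numbers
it computes and says what they mean. A thin CLI mirrors the file-based
workflow:

```bash
cnvrkit simulate --seed 5 --out sim/
cnvrkit run --config pipeline.yaml     # clean -> CNVRs -> consensus -> genes
```

## Layout

```
src/cnvrkit/     types, io, cleaning, cnvr, compare, mapdiff, genes,
                 simulate, pipeline, plots, cli
tests/           unit + property suites (hypothesis), brute-force oracles,
                 acceptance checks
examples/        one narrative script per capability
docs/methods.md  model, parameters, simulator scope, numerical conventions
```
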