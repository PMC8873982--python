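# Methods

cnvrkit implements the post-calling stage of a SNP-array copy-number study:
it starts from the CNV segments two callers (PennCNV and GenomeStudio's
CNVPartition plug-in) have already inferred from Log R Ratio / B-allele
frequency signal, and carries them through cleaning, population-level region
building, cross-caller and cross-assembly comparison, consensus calling and
gene annotation. The callers themselves are out of scope; their output
formats are the package's inputs.

## Coordinate and data model

All intervals are 1-based and closed, the convention of both caller
formats; lengths are `end - start + 1`. BED export converts to 0-based
half-open at the boundary. Chromosome labels are bare strings without a
`chr` prefix, and the analysis is restricted to autosomes (sex chromosomes
are skipped by the readers by default, since array CNV calling on X/Y in a
single-sex cohort is unreliable). A CNV call carries a copy-number state in
{0, 1, 3, 4}; state 2 is diploid and is rejected as a parse-level error.

## Cleaning

Three filters sit between raw caller output and region building, with these
defaults (all configurable through `CleanConfig`):

| parameter | default | role |
|---|---|---|
| `lrr_sd_max` | 0.30 | exclude samples with noisy total intensity |
| `baf_drift_max` | 0.005 | exclude samples with allelic-ratio drift |
| `wave_factor_abs_max` | 0.1 | exclude samples with genomic-wave artefact |
| `merge_fraction` | 0.2 | gap-merge threshold for adjacent same-state calls |
| `drop_length_mb` | 5 | discard calls longer than this (Mb) |

Sample-QC comparisons are strict (`>`), so a sample sitting exactly at a
threshold is kept — the thresholds are phrased as "larger than" limits.

Gap merging combines two same-sample, same-chromosome, same-state
neighbours A and B when `gap / denom < fraction` with
`gap = B.start − A.end − 1`. The denominator is ambiguous in common usage
("total length of the CNVs"); cnvrkit defaults to the full span
`A.start..B.end` (both calls plus the gap) and offers `len(A) + len(B)` via
`merge_denominator="lengths"`. The sweep runs left to right and repeats to
a fixed point, which makes the result independent of input order; the unit
suite checks equivalence with an exhaustive any-pair merge oracle.
Overlapping same-state calls in one sample should not occur in caller
output, but are merged unconditionally with a warning rather than dropped.
Gap merging is applied to PennCNV output only; CNVPartition segments are
used as exported (its own confidence floor, default 35, is applied at
parse time).

The length cap is strict: a call of exactly 5,000,000 bp is kept. Calls
above the cap at array resolution are overwhelmingly hybridisation or
wave artefacts.

## CNV regions

A CNV region (CNVR) is a connected component of the interval-overlap graph
on one chromosome, where overlap means **at least one shared basepair**
(`A.start <= B.end and B.start <= A.end`). Two calls that touch
end-to-start share no basepair and do not merge — a deliberate reading of
the ≥1-bp rule that the test oracle reproduces on a doubled-coordinate
grid so adjacency stays observable. Regions are classified gain (all
member states > 2), loss (all < 2) or mixed (both present), and numbered
`CNVR_k` in (chromosome, start) order.

A region's **frequency is its distinct-sample carrier count**
(`n_samples`), not its raw call count; `n_calls` is reported alongside.
Genome coverage divides the summed region lengths by the summed
chromosome lengths of the supplied genome build (the denominator is
explicit because published coverages often leave it unstated).

## Comparison and consensus

CNV-level comparison is directional and runs at two levels: individual
(an A call is overlapped only by a same-sample B call sharing ≥1 bp;
measures method similarity) and population (sample identity ignored;
measures repeatability). The population percentage provably dominates the
individual one, and the suite asserts this on random cohorts. A call
overlapping several partners counts once.

CNVR-level comparison reports all intersecting pairs and an overlapped
length computed as the basepair size of `union(A) ∩ union(B)`, i.e. the
union of pairwise intersections — a basepair covered by several pairs is
counted once. This accounting choice is checked against a per-basepair
coverage oracle.

Consensus CNVRs come from pooling the call lists of both callers,
re-running region generation on the pool, and keeping regions whose
distinct-sample count (each sample counted once even if both callers
report it) reaches `ceil(min(sample sizes) × proportion)` with
`proportion = 0.05`. The ceiling is computed in decimal arithmetic so that
e.g. a 400-sample cohort yields exactly 20, not 21 through float error.
The comparison is inclusive (`>=`), with `>` selectable, since published
phrasings mix the two. Consensus genes use the same threshold on the same
distinct-sample basis, which guarantees (and the suite asserts) that a
consensus gene always lies in at least one consensus region.

External cross-validation (`compare_to_database`) treats a study region as
validated when it shares ≥1 bp with any region of an external list (e.g. a
DGVa-style compilation), and reports count and length fractions;
`flag_known_artifacts` marks study regions intersecting a blacklist of
known assembly-error intervals.

## SNP-map comparison

Two manifests of the same array under different assemblies are compared by
marker name. Each name in the union falls in exactly one of seven
categories (same chromosome, different chromosomes, unknown in both/one,
missing from one); the partition property is asserted for arbitrary maps.
"Same chromosome" deliberately ignores position differences — order
disagreement is summarised separately as an exact discordant-pair
(inversion) count per chromosome, computed by merge sort and verified
against an O(n²) scan. This numeric summary is an addition over the usual
purely visual dot-plot treatment and is labelled as such. SNP density uses
explicit chromosome lengths when a genome file is given and falls back to
the last marker position with a warning (the fallback slightly inflates
density).

Unknown-position sentinels (chromosome `0`, empty, `NA`, `Un*`, or
position ≤ 0) are configurable, since export conventions vary.

## The synthetic cohort generator

`simulate_cohort` emulates the structure of a real array cohort so every
stage is testable without genotype data: 400 samples over 29 autosomes of
10 Mb with a marker every 2 kb (~145k markers, the scale of a 150K chip).
Eight planted region archetypes span gain/loss/mixed types with carrier
frequencies 0.30, 0.25, 0.15, 0.08, 0.05, 0.05, 0.02 and 0.01 — bracketing
the 5% consensus proportion from both sides. Carriers are i.i.d. Bernoulli
draws at the target frequency; each carrier's event gets breakpoints
jittered uniformly within ±2% of the region span (5% in the stress test),
a copy-number state drawn per type (one- and three-copy states common,
zero- and four-copy rare, the qualitative pattern of real caller output),
and is observed by each caller with a per-caller detection probability
(default 1.0). False-positive singleton calls arrive Poisson(0.5) per
sample per caller; 2% of samples get a failing signal-QC record. The map
pair plants per-marker discrepancies at rates echoing a real old-vs-new
assembly comparison (~10% unplaced in the older map, <1% per other
category) plus locally shuffled windows for order discordance. Genes are
placed deterministically inside each archetype and in archetype-free
territory.

A `TruthManifest` records planted regions with realized carrier lists per
caller, per-marker map categories, gene placements, QC failures and
oversize artefacts. Identical configs (including seed) produce
byte-identical files. Recovery properties are judged against *realized*
carrier counts, not target frequencies, because a 5%-target archetype can
legitimately draw fewer than the threshold number of carriers.

What the simulator does **not** model — and hence what passing tests do
not show about real data: linkage disequilibrium and marker-density
heterogeneity, pedigree relatedness between carriers, caller-specific
breakpoint biases (both simulated callers see the same true event),
intensity-level artefacts (waves, batch effects) beyond the summary QC
statistics, and realistic chromosome-length variation. The scaled-down
test configuration (5 × 2 Mb chromosomes, 60 samples) keeps the default
suite in seconds; the full-size configuration is exercised in the
acceptance property test.

## Numerical and reporting conventions

Report rounding is two decimals, half away from zero (so a mean of
148,823.5 bp prints as 148,824); raw values are kept unrounded in the data
structures. Region/gene orderings break ties deterministically
(chromosome numeric-first sort, then start, then name), so reruns are
reproducible file-for-file. Degenerate inputs are defined: empty call
lists produce empty reports with a warning, an empty annotation file an
empty gene list, chromosomes without markers a density of zero.

## Known limitations

* No liftover support: cross-assembly region comparison is only possible
  through shared marker anchors or by name at the gene level; the package
  compares gene *sets* across assemblies rather than converting
  coordinates.
* CNVR boundaries are the union of member calls; no breakpoint
  re-estimation from signal is attempted.
* PennCNV confidence values are parsed but unused by default; only the
  CNVPartition confidence floor filters calls.
* Overlap-enrichment significance (permutation testing) is deliberately
  out of scope; all comparisons are descriptive.
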