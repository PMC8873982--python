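"""Compare two callers' CNVs at the individual and population level, then
intersect their CNVR lists.

Individual-level overlap requires the same sample to carry the call in
both lists (method similarity); population-level ignores sample identity
(repeatability) and is always at least as high.
"""
from cnvrkit import (
    SimConfig,
    call_cnvr,
    compare_cnv_individual,
    compare_cnv_population,
    compare_cnvr,
    simulate_cohort,
)

# thin one caller to 70% detection so the two lists genuinely differ
bundle = simulate_cohort(SimConfig(
    seed=42, caller_detection_prob=(("penncnv", 1.0), ("cnvpartition", 0.7))))
penn, part = bundle.penncnv_calls, bundle.cnvpartition_calls

for label, rep in [("individual", compare_cnv_individual(penn, part)),
                   ("population", compare_cnv_population(penn, part))]:
    print(f"{label} level: {rep.a.pct_overlapped:.1f}% of PennCNV calls "
          f"overlapped vs {rep.b.pct_overlapped:.1f}% of CNVPartition calls")

pairs, rep = compare_cnvr(call_cnvr(penn, id_prefix="PENN"),
                          call_cnvr(part, id_prefix="PART"))
print(f"\nCNVR level: {rep.n_a_hit} of {rep.n_a} PennCNV regions intersect "
      f"{rep.n_b_hit} of {rep.n_b} CNVPartition regions")
print(f"overlapped length {rep.overlap_bp:,} bp = {rep.pct_len_a:.1f}% / "
      f"{rep.pct_len_b:.1f}% of each side's total")
# The overlapped length is the union of pairwise intersections, so a
# basepair shared by several region pairs is only counted once.
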