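"""Standardisation and quality filtering of raw CNV calls.

Three filters are applied between caller output and CNVR generation:

1. per-sample exclusion on signal quality — LRR standard deviation > 0.30,
   BAF drift > 0.005, or |wave factor| > 0.1 (all strict);
2. merging of adjacent same-state calls whose gap is less than a fraction
   (default 0.2) of the merged span, applied iteratively to a fixed point;
3. discarding calls longer than a cap (default 5 Mb), which at SNP-array
   resolution are almost always hybridisation artefacts.

A Table-style summary (per-state counts, length statistics, calls per
individual) is produced after cleaning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from ._utils import round_report
from .types import CnvCall, ConfigError, SampleQcRecord, SchemaError

log = logging.getLogger(__name__)

#: length-class bin edges (bp) for the summary histogram
LENGTH_BIN_EDGES = (50_000, 100_000, 500_000, 1_000_000)
LENGTH_BIN_LABELS = ("<50kb", "50-100kb", "100-500kb", "0.5-1Mb", ">=1Mb")


@dataclass(frozen=True)
class CleanConfig:
    """Thresholds for the cleaning stage.

    Defaults follow standard PennCNV post-processing practice: 5-Mb length
    cap, 0.2 gap fraction, LRR SD 0.30, BAF drift 0.005, |wave factor| 0.1.
    ``merge_denominator`` selects the gap-ratio denominator: ``"span"``
    (whole region from A.start to B.end, the default) or ``"lengths"``
    (len(A) + len(B) only).
    """

    drop_length_mb: float = 5.0
    merge_fraction: float = 0.2
    lrr_sd_max: float = 0.30
    baf_drift_max: float = 0.005
    wave_factor_abs_max: float = 0.1
    merge_denominator: str = "span"

    def __post_init__(self) -> None:
        for name in ("drop_length_mb", "lrr_sd_max", "baf_drift_max",
                     "wave_factor_abs_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 < self.merge_fraction < 1):
            raise ConfigError("merge_fraction must be in (0, 1)")
        if self.merge_denominator not in ("span", "lengths"):
            raise ConfigError("merge_denominator must be 'span' or 'lengths'")


def filter_samples_by_qc(
    qc: Sequence[SampleQcRecord],
    cfg: CleanConfig = CleanConfig(),
) -> Tuple[List[str], Dict[str, List[str]]]:
    """Split samples into kept ids and excluded ids with reasons.

    A sample is excluded iff lrr_sd > lrr_sd_max OR baf_drift >
    baf_drift_max OR |wave_factor| > wave_factor_abs_max; comparisons are
    strict, so values exactly at a threshold pass.
    """
    ids = [r.sample_id for r in qc]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise SchemaError(f"duplicate sample ids in QC table: {dupes}")
    kept: List[str] = []
    excluded: Dict[str, List[str]] = {}
    for r in qc:
        reasons = []
        if r.lrr_sd > cfg.lrr_sd_max:
            reasons.append("LRR_SD")
        if r.baf_drift > cfg.baf_drift_max:
            reasons.append("BAF_DRIFT")
        if abs(r.wave_factor) > cfg.wave_factor_abs_max:
            reasons.append("WAVE_FACTOR")
        if reasons:
            excluded[r.sample_id] = reasons
        else:
            kept.append(r.sample_id)
    return kept, excluded


def _merge_pair(a: CnvCall, b: CnvCall) -> CnvCall:
    confs = [c.conf for c in (a, b) if c.conf is not None]
    return replace(
        a,
        start=a.start,
        end=max(a.end, b.end),
        n_snp=a.n_snp + b.n_snp,
        conf=min(confs) if confs else None,
    )


def merge_adjacent_calls(
    calls: Sequence[CnvCall],
    fraction: float = 0.2,
    *,
    denominator: str = "span",
) -> List[CnvCall]:
    """Merge same-sample/chromosome/state neighbours separated by small gaps.

    Two neighbours A, B (A.start <= B.start) are merged iff::

        gap / denom < fraction,  gap = B.start - A.end - 1

    with ``denom`` the full span A.start..B.end (default) or
    len(A) + len(B).  The sweep runs left to right and is repeated until a
    fixed point is reached, so the result does not depend on input order.
    Overlapping calls within a group (negative gap — callers should not
    produce them) are merged unconditionally with a warning.
    """
    groups: Dict[tuple, List[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.caller, c.build, c.sample_id, c.chrom, c.cn), []).append(c)
    out: List[CnvCall] = []
    for group in groups.values():
        group = sorted(group, key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged: List[CnvCall] = [group[0]]
            for nxt in group[1:]:
                cur = merged[-1]
                gap = nxt.start - cur.end - 1
                if gap < 0:
                    log.warning(
                        "overlapping same-state calls merged: %s and %s",
                        cur.key, nxt.key,
                    )
                    do_merge = True
                else:
                    if denominator == "span":
                        denom = max(cur.end, nxt.end) - cur.start + 1
                    else:
                        denom = cur.length + nxt.length
                    do_merge = gap / denom < fraction
                if do_merge:
                    merged[-1] = _merge_pair(cur, nxt)
                    changed = True
                else:
                    merged.append(nxt)
            group = merged
        out.extend(group)
    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end, c.cn))
    return out


def drop_long_cnvs(
    calls: Sequence[CnvCall],
    drop_length_mb: float = 5.0,
) -> Tuple[List[CnvCall], List[CnvCall]]:
    """Partition calls into (kept, dropped); dropped iff length > cap (strict)."""
    cap = int(round(drop_length_mb * 1_000_000))
    kept = [c for c in calls if c.length <= cap]
    dropped = [c for c in calls if c.length > cap]
    return kept, dropped


@dataclass(frozen=True)
class CnvSummary:
    """Cohort-level CNV statistics (per-state counts and length stats)."""

    n_individuals: int
    n_cnvs: int
    cnvs_per_individual: float  # exact; round to 2 dp for reports
    per_state_counts: Mapping[int, int]
    per_state_length_stats: Mapping[int, Tuple[float, int, int]]  # mean, min, max
    length_bins: Mapping[str, int]

    def to_rows(self) -> List[dict]:
        """Report rows with 2-dp rounding, one per copy-number state."""
        rows = []
        for cn in sorted(self.per_state_counts):
            mean_len, min_len, max_len = self.per_state_length_stats[cn]
            rows.append(
                {
                    "cn": cn,
                    "type": "duplication" if cn > 2 else "deletion",
                    "n_cnvs": self.per_state_counts[cn],
                    "mean_length": round_report(mean_len, 0),
                    "min_length": min_len,
                    "max_length": max_len,
                }
            )
        return rows


def summarize_cnvs(calls: Sequence[CnvCall], n_individuals: int) -> CnvSummary:
    """Summarise cleaned calls: counts and length statistics per CN state.

    ``cnvs_per_individual`` is total calls / ``n_individuals`` (the number
    of samples that survived QC, not the number with at least one call).
    """
    if n_individuals <= 0:
        raise ConfigError("n_individuals must be > 0")
    per_state: Dict[int, List[int]] = {}
    bins = {label: 0 for label in LENGTH_BIN_LABELS}
    for c in calls:
        per_state.setdefault(c.cn, []).append(c.length)
        for edge, label in zip(LENGTH_BIN_EDGES, LENGTH_BIN_LABELS):
            if c.length < edge:
                bins[label] += 1
                break
        else:
            bins[LENGTH_BIN_LABELS[-1]] += 1
    counts = {cn: len(v) for cn, v in per_state.items()}
    stats = {
        cn: (sum(v) / len(v), min(v), max(v)) for cn, v in per_state.items()
    }
    total = len(calls)
    return CnvSummary(
        n_individuals=n_individuals,
        n_cnvs=total,
        cnvs_per_individual=total / n_individuals,
        per_state_counts=counts,
        per_state_length_stats=stats,
        length_bins=bins,
    )


def clean_calls(
    calls: Sequence[CnvCall],
    cfg: CleanConfig = CleanConfig(),
    *,
    kept_samples: Iterable[str] | None = None,
    merge: bool = True,
) -> Tuple[List[CnvCall], List[CnvCall]]:
    """Full cleaning stage: sample filter, optional gap-merge, length cap.

    Returns (cleaned calls, dropped over-length calls).  ``merge`` should be
    enabled for PennCNV output; CNVPartition segments are not gap-merged by
    default.
    """
    work = list(calls)
    if kept_samples is not None:
        keep = set(kept_samples)
        work = [c for c in work if c.sample_id in keep]
    if merge:
        work = merge_adjacent_calls(work, cfg.merge_fraction,
                                    denominator=cfg.merge_denominator)
    return drop_long_cnvs(work, cfg.drop_length_mb)
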