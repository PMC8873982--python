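"""Static publication-style figures: CNVR genome map, SNP-order dot plots."""
from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ._utils import chrom_sort_key
from .cnvr import cnvr_summary
from .mapdiff import ConcordanceReport
from .types import GAIN, LOSS, MIXED, CnvRegion, GenomeBuild

TYPE_COLORS = {GAIN: "#1f77b4", LOSS: "#d62728", MIXED: "#2ca02c"}


def render_cnvr_map(
    regions: Sequence[CnvRegion],
    genome: GenomeBuild,
    path: str | Path,
    *,
    consensus: Sequence[CnvRegion] = (),
    title: str = "CNV region distribution",
) -> Path:
    """One horizontal panel per chromosome: region glyphs coloured by type,
    consensus regions underlined, per-chromosome coverage % printed.

    The printed coverage labels are the same values
    :func:`cnvrkit.cnvr.cnvr_summary` reports, so nothing in the figure is
    plot-only arithmetic.
    """
    chroms = sorted(genome.chrom_lengths, key=chrom_sort_key)
    coverage = cnvr_summary(regions, genome).per_chrom_coverage_pct if regions else {}
    fig, ax = plt.subplots(figsize=(10, 0.32 * len(chroms) + 1.2))
    ymap = {c: len(chroms) - i for i, c in enumerate(chroms)}
    for c in chroms:
        y = ymap[c]
        ax.hlines(y, 0, genome.chrom_lengths[c] / 1e6, color="0.8", lw=3, zorder=1)
        ax.text(genome.chrom_lengths[c] / 1e6 + 0.5, y,
                f"{coverage.get(c, 0.0):.1f}%", va="center", fontsize=7)
    for r in regions:
        y = ymap[r.chrom]
        ax.hlines(y, r.start / 1e6, max(r.end / 1e6, r.start / 1e6 + 0.03),
                  color=TYPE_COLORS[r.type], lw=6, zorder=2)
    for r in consensus:
        y = ymap[r.chrom]
        ax.hlines(y - 0.3, r.start / 1e6, max(r.end / 1e6, r.start / 1e6 + 0.03),
                  color="purple", lw=2, zorder=3)
    ax.set_yticks([ymap[c] for c in chroms], chroms, fontsize=7)
    ax.set_xlabel("position (Mb)")
    ax.set_title(title)
    handles = [plt.Line2D([], [], color=col, lw=6, label=t)
               for t, col in TYPE_COLORS.items()]
    handles.append(plt.Line2D([], [], color="purple", lw=2, label="consensus"))
    ax.legend(handles=handles, loc="lower right", fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_position_concordance(
    report: ConcordanceReport,
    path: str | Path,
    *,
    max_panels: int = 30,
) -> Path:
    """Rank-vs-rank dot plot per chromosome; off-diagonal points are
    markers whose order differs between the two maps."""
    chroms = list(report.per_chrom)[:max_panels]
    n = max(1, len(chroms))
    ncol = min(6, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow),
                             squeeze=False)
    for i, chrom in enumerate(chroms):
        ax = axes[i // ncol][i % ncol]
        c = report.per_chrom[chrom]
        ax.plot(range(c.n_markers), c.ranks_b, ".", ms=1.5, color="#1f77b4")
        ax.set_title(f"chr{chrom} ({c.n_discordant_pairs} disc.)", fontsize=7)
        ax.tick_params(labelsize=6)
    for j in range(len(chroms), nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.suptitle("SNP order: map A rank vs map B rank")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
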