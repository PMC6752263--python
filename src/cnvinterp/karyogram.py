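"""The digital karyogram: genome-wide depth-distribution heatmaps and
B-allele-frequency panels.

Normalized depth bins (filtered against a population-variable-position
mask) are grouped into 100-kb segments and each segment's depth
distribution becomes one heatmap column; B-allele fractions follow the
same protocol with 500-kb segments. The result makes whole-chromosome
events — trisomies, large deletions, mosaic aneuploidy, uniparental
isodisomy (diploid depth, no mid-range BAF) — visible at a glance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import GenomeLayout, ValidationError, merge_intervals
from .depth import NormalizedProfile, _overlap_weights


@dataclass
class KaryogramMatrix:
    """Per-chromosome heatmap: value-bin histograms per genomic segment."""

    layout: GenomeLayout
    segment_width: int
    value_edges: np.ndarray
    histograms: dict  # chrom -> array (n_value_bins, n_segments)

    def total_mass(self) -> int:
        return int(sum(h.sum() for h in self.histograms.values()))

    def empty_columns(self, chrom) -> np.ndarray:
        return self.histograms[chrom].sum(axis=0) == 0


@dataclass
class BafMatrix:
    """Per-chromosome B-allele fractions grouped into genomic segments."""

    layout: GenomeLayout
    segment_width: int
    columns: dict  # chrom -> list of arrays of fractions


def default_value_edges(step: float = 0.1, vmax: float = 4.0) -> np.ndarray:
    return np.arange(0.0, vmax + step / 2, step)


def depth_matrix(nprof: NormalizedProfile, mask: Sequence = (),
                 segment_width: int = 100_000,
                 value_edges: Optional[np.ndarray] = None) -> KaryogramMatrix:
    """Histogram normalized depth per fixed genomic segment.

    Depth bins overlapping the variable-position mask by more than half
    their length are excluded; surviving bins are assigned to segments by
    midpoint. Values outside the edge range are clipped into the outer
    histogram bins so column mass is conserved.
    """
    if value_edges is None:
        value_edges = default_value_edges()
    ivs = [r.interval if hasattr(r, "interval") else r for r in mask]
    merged = merge_intervals(ivs) if ivs else []
    by_chrom: dict = {}
    for m in merged:
        by_chrom.setdefault(m.chrom, []).append(m)
    hists = {}
    for chrom in nprof.chroms():
        cb = nprof.bins[chrom]
        ncol = -(-nprof.layout.length(chrom) // segment_width)
        H = np.zeros((len(value_edges) - 1, ncol))
        if len(cb):
            keep = np.ones(len(cb), dtype=bool)
            if chrom in by_chrom:
                ov = np.zeros(len(cb))
                for m in by_chrom[chrom]:
                    ov += _overlap_weights(cb.starts, cb.ends, m)
                keep = ov <= 0.5 * cb.widths
            mids = (cb.starts[keep] + cb.ends[keep]) // 2
            cols = mids // segment_width
            vals = np.clip(cb.values[keep], value_edges[0],
                           value_edges[-1] - 1e-9)
            for col in np.unique(cols):
                h, _ = np.histogram(vals[cols == col], bins=value_edges)
                H[:, col] = h
        hists[chrom] = H
    return KaryogramMatrix(nprof.layout, segment_width, value_edges, hists)


def baf_matrix(variants: pd.DataFrame, layout: GenomeLayout,
               segment_width: int = 500_000) -> BafMatrix:
    """Group variant B-allele fractions into fixed genomic segments.

    `variants` needs chrom/pos/baf columns with baf in [0, 1]; variants
    are assigned by position, and a segment with no variants yields an
    empty column.
    """
    if not {"chrom", "pos", "baf"} <= set(variants.columns):
        raise ValidationError("variant table needs chrom, pos, baf columns")
    if len(variants) and not (
        (variants["baf"] >= 0) & (variants["baf"] <= 1)
    ).all():
        raise ValidationError("B-allele fractions must lie in [0, 1]")
    columns = {}
    for chrom in layout.names:
        ncol = -(-layout.length(chrom) // segment_width)
        sub = variants[variants["chrom"] == chrom]
        cols = (sub["pos"] // segment_width).to_numpy() if len(sub) else np.array([])
        bafs = sub["baf"].to_numpy() if len(sub) else np.array([])
        columns[chrom] = [bafs[cols == i] for i in range(ncol)]
    return BafMatrix(layout, segment_width, columns)


def render(kmat: KaryogramMatrix, bafmat: Optional[BafMatrix] = None,
           path: str = "karyogram.png", dpi: int = 100) -> str:
    """Render the karyogram: one depth-heatmap panel per chromosome, with
    a BAF scatter panel beneath when BAF data is supplied. Deterministic
    layout and bytes for fixed inputs and renderer settings."""
    chroms = [c for c in kmat.layout.names if c in kmat.histograms]
    if not chroms:
        raise ValidationError("empty genome: nothing to render")
    rows = 2 if bafmat is not None else 1
    fig, axes = plt.subplots(
        rows, len(chroms),
        figsize=(max(2.0, 2.5 * len(chroms)), 3.0 * rows),
        squeeze=False,
    )
    for j, chrom in enumerate(chroms):
        H = kmat.histograms[chrom]
        ax = axes[0][j]
        ax.imshow(H, origin="lower", aspect="auto", cmap="viridis",
                  extent=(0, H.shape[1], kmat.value_edges[0],
                          kmat.value_edges[-1]))
        ax.set_title(chrom, fontsize=8)
        if j == 0:
            ax.set_ylabel("copy number")
        if bafmat is not None:
            axb = axes[1][j]
            cols = bafmat.columns.get(chrom, [])
            for i, fr in enumerate(cols):
                if len(fr):
                    axb.plot(np.full(len(fr), i + 0.5), fr, ".", ms=1.5,
                             color="#33557a", alpha=0.6)
            axb.set_ylim(-0.02, 1.02)
            axb.set_xlim(0, max(1, len(cols)))
            if j == 0:
                axb.set_ylabel("B-allele fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi, metadata=_deterministic_metadata(path))
    plt.close(fig)
    return path


def _deterministic_metadata(path):
    # strip renderer timestamps so identical inputs give identical bytes
    if str(path).endswith(".svg"):
        return {"Date": None}
    if str(path).endswith(".png"):
        return {"Software": None}
    return None


def variance_mask_from_panel(panel, quantile: float = 0.99):
    """Derive a variable-position mask from a panel: grid cells whose
    cross-sample depth variance exceeds the given quantile, merged into
    intervals. A synthetic stand-in for a curated population mask."""
    from .core import Interval

    profiles = list(panel.profiles.values())
    out = []
    for chrom in panel.layout.names:
        if chrom not in profiles[0].values:
            continue
        stack = np.vstack([p.values[chrom] for p in profiles])
        var = np.nanvar(stack, axis=0)
        finite = var[np.isfinite(var)]
        if not len(finite):
            continue
        cut = np.quantile(finite, quantile)
        flag = np.isfinite(var) & (var > cut)
        starts, ends = profiles[0].cell_bounds(chrom)
        out.extend(Interval(chrom, int(s), int(e))
                   for s, e, f in zip(starts, ends, flag) if f)
    return merge_intervals(out) if out else []
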