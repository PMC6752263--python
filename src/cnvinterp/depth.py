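"""Depth-bin construction, per-sample normalization, and fixed-grid resampling.

The unit of analysis is the depth bin: a genomic window sized so that a
fixed expected number of reads (default 100) map inside it at diploid
state. Normalization is sample-internal (median autosomal scaling), which
is what makes the pipeline batch-free: no cross-sample model is ever fit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    GenomeLayout,
    Interval,
    NoCoverageError,
    ValidationError,
    merge_intervals,
)

log = logging.getLogger(__name__)


@dataclass
class ChromBins:
    """Sorted, non-overlapping bins on one chromosome."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.starts)
        if not (len(self.ends) == n and len(self.values) == n):
            raise ValidationError("bin arrays must have equal length")
        if n:
            if np.any(self.ends <= self.starts):
                raise ValidationError("bin end must exceed bin start")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValidationError("bins overlap or are unsorted")

    def __len__(self):
        return len(self.starts)

    @property
    def widths(self):
        return self.ends - self.starts


@dataclass
class DepthProfile:
    """Per-sample binned read counts along a genome."""

    layout: GenomeLayout
    bins: dict  # chrom -> ChromBins
    sample_id: str = "sample"
    sex: str = "female"

    def __post_init__(self):
        for chrom, cb in self.bins.items():
            ln = self.layout.length(chrom)
            if len(cb) and cb.ends[-1] > ln:
                raise ValidationError(f"bins extend past end of {chrom}")
            if len(cb) and np.any(cb.values < 0):
                raise ValidationError(f"negative depth on {chrom}")

    @property
    def n_bins(self):
        return sum(len(cb) for cb in self.bins.values())

    def chroms(self):
        return [c for c in self.layout.names if c in self.bins]


@dataclass
class NormalizedProfile(DepthProfile):
    """Binned continuous copy-number values (diploid expectation = 2.0)."""

    norm_constant: float = 1.0

    def __post_init__(self):  # values are copy numbers; negativity still invalid
        super().__post_init__()


@dataclass
class GriddedProfile:
    """Fixed-width grid of copy values; NaN marks cells with no source data."""

    layout: GenomeLayout
    grid_width: int
    values: dict  # chrom -> float array of length ceil(chrom_len / width)
    sample_id: str = "sample"
    sex: str = "female"

    def cell_bounds(self, chrom):
        n = len(self.values[chrom])
        starts = np.arange(n, dtype=np.int64) * self.grid_width
        ends = np.minimum(starts + self.grid_width, self.layout.length(chrom))
        return starts, ends


def make_bins(coverage: dict, layout: GenomeLayout, expected_reads_per_bin: int = 100,
              sample_id: str = "sample", sex: str = "female") -> DepthProfile:
    """Aggregate per-base read counts into fixed-width depth bins.

    `coverage` maps chromosome -> per-base read-start counts. Bin width is
    round(expected_reads_per_bin / genome-wide mean per-base count), so a
    bin holds ~expected_reads_per_bin reads at diploid state. The last bin
    of each chromosome may be short.
    """
    total = sum(float(np.sum(np.asarray(v))) for v in coverage.values())
    glen = sum(len(np.asarray(v)) for v in coverage.values())
    if glen == 0 or total <= 0:
        raise ValidationError("cannot size bins: zero coverage genome-wide")
    mean_cov = total / glen
    width = max(1, int(round(expected_reads_per_bin / mean_cov)))
    bins = {}
    for chrom, cov in coverage.items():
        cov = np.asarray(cov, dtype=np.float64)
        if len(cov) != layout.length(chrom):
            raise ValidationError(
                f"coverage array length mismatch on {chrom}: "
                f"{len(cov)} vs layout {layout.length(chrom)}"
            )
        starts = np.arange(0, len(cov), width, dtype=np.int64)
        ends = np.minimum(starts + width, len(cov))
        sums = np.add.reduceat(cov, starts)
        bins[chrom] = ChromBins(starts, ends, sums)
    return DepthProfile(layout, bins, sample_id=sample_id, sex=sex)


def normalize(profile: DepthProfile) -> NormalizedProfile:
    """Scale counts to copy number via median autosomal count density.

    value_i = 2 * density_i / median(autosomal densities). Sex chromosomes
    share the autosomal constant, so an XY male sits near 1.0 on X. The
    median makes the constant robust to large CNVs and whole-chromosome
    aneuploidy. Idempotent up to floating tolerance on equal-width bins.
    """
    dens = []
    for chrom in profile.chroms():
        if profile.layout.is_autosome(chrom):
            cb = profile.bins[chrom]
            if len(cb):
                dens.append(cb.values / cb.widths)
    if not dens:
        raise ValidationError("no autosomal bins to normalize against")
    med = float(np.median(np.concatenate(dens)))
    if med <= 0:
        raise ValidationError("median autosomal depth is zero; cannot normalize")
    bins = {}
    for chrom, cb in profile.bins.items():
        vals = 2.0 * (cb.values / cb.widths) / med
        bins[chrom] = ChromBins(cb.starts.copy(), cb.ends.copy(), vals)
    return NormalizedProfile(
        profile.layout, bins, sample_id=profile.sample_id, sex=profile.sex,
        norm_constant=med,
    )


def to_grid(nprof: NormalizedProfile, grid_width: int = 300) -> GriddedProfile:
    """Resample a normalized profile onto a fixed uniform coordinate grid.

    Each grid cell takes the length-weighted mean of overlapping source
    bins; cells with no overlapping data are NaN (missing), never zero.
    The 300-bp default matches a compact panel storage grid.
    """
    if grid_width <= 0:
        raise ValidationError("grid width must be positive")
    values = {}
    for chrom in nprof.chroms():
        cb = nprof.bins[chrom]
        clen = nprof.layout.length(chrom)
        ncell = -(-clen // grid_width)
        wsum = np.zeros(ncell)
        vsum = np.zeros(ncell)
        for s, e, v in zip(cb.starts, cb.ends, cb.values):
            c0 = s // grid_width
            c1 = (e - 1) // grid_width
            cells = np.arange(c0, c1 + 1)
            lo = np.maximum(cells * grid_width, s)
            hi = np.minimum((cells + 1) * grid_width, e)
            w = (hi - lo).astype(np.float64)
            np.add.at(wsum, cells, w)
            np.add.at(vsum, cells, w * v)
        with np.errstate(invalid="ignore", divide="ignore"):
            cellvals = np.where(wsum > 0, vsum / np.maximum(wsum, 1e-300), np.nan)
        values[chrom] = cellvals
    return GriddedProfile(nprof.layout, grid_width, values,
                          sample_id=nprof.sample_id, sex=nprof.sex)


def _overlap_weights(starts, ends, interval):
    lo = np.maximum(starts, interval.start)
    hi = np.minimum(ends, interval.end)
    return np.maximum(0, hi - lo).astype(np.float64)


def mean_copy(obj, interval: Interval) -> float:
    """Length-weighted mean copy value of a profile over an interval.

    Works on NormalizedProfile and GriddedProfile; missing grid cells are
    excluded from the weighting. Raises NoCoverageError when the interval
    overlaps no data, ValidationError when it falls off the chromosome.
    """
    if isinstance(obj, GriddedProfile):
        obj.layout.validate_interval(interval)
        if interval.chrom not in obj.values:
            raise NoCoverageError(f"no grid data on {interval.chrom}")
        starts, ends = obj.cell_bounds(interval.chrom)
        vals = obj.values[interval.chrom]
    elif isinstance(obj, NormalizedProfile):
        obj.layout.validate_interval(interval)
        if interval.chrom not in obj.bins:
            raise NoCoverageError(f"no depth bins on {interval.chrom}")
        cb = obj.bins[interval.chrom]
        starts, ends, vals = cb.starts, cb.ends, cb.values
    else:
        raise TypeError("mean_copy expects a NormalizedProfile or GriddedProfile")
    w = _overlap_weights(starts, ends, interval)
    ok = (w > 0) & ~np.isnan(vals)
    if not np.any(ok):
        raise NoCoverageError(f"no depth data overlapping {interval}")
    return float(np.sum(w[ok] * vals[ok]) / np.sum(w[ok]))


def covered_fraction(grid: GriddedProfile, interval: Interval) -> float:
    """Fraction of an interval's bases lying in non-missing grid cells."""
    grid.layout.validate_interval(interval)
    if interval.chrom not in grid.values:
        return 0.0
    starts, ends = grid.cell_bounds(interval.chrom)
    vals = grid.values[interval.chrom]
    w = _overlap_weights(starts, ends, interval)
    return float(np.sum(w[~np.isnan(vals)]) / interval.length)


def mask_bins(nprof: NormalizedProfile, regions, max_overlap: float = 0.5
              ) -> NormalizedProfile:
    """Drop bins whose overlap with the union of `regions` exceeds
    max_overlap of the bin length. Used to mask the calling-time
    (centromere-minimal) gray list before segmentation."""
    ivs = [r.interval if hasattr(r, "interval") else r for r in regions]
    merged = merge_intervals(ivs) if ivs else []
    by_chrom: dict = {}
    for m in merged:
        by_chrom.setdefault(m.chrom, []).append(m)
    bins = {}
    dropped = 0
    for chrom, cb in nprof.bins.items():
        if chrom not in by_chrom or not len(cb):
            bins[chrom] = cb
            continue
        ov = np.zeros(len(cb))
        for m in by_chrom[chrom]:
            ov += _overlap_weights(cb.starts, cb.ends, m)
        keep = ov <= max_overlap * cb.widths
        dropped += int(np.sum(~keep))
        bins[chrom] = ChromBins(cb.starts[keep], cb.ends[keep], cb.values[keep])
    if dropped:
        log.info("masked %d depth bins overlapping the calling gray list", dropped)
    return NormalizedProfile(nprof.layout, bins, sample_id=nprof.sample_id,
                             sex=nprof.sex, norm_constant=nprof.norm_constant)
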