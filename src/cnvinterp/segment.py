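"""Circular binary segmentation of normalized depth and CNV call formation.

The segmenter follows the classic CBS recursion: for a candidate segment,
find the circular arc whose mean most differs from the rest (max
|t|-statistic), assess it with a permutation test, and split when the
permutation p-value falls below alpha; recurse on the pieces. Calls are
then formed by rounding segment means against the expected ploidy, with
support filtering, adjacent-call merging, mosaic labeling and a linear
mixture purity estimate layered on top.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    GAIN,
    LOSS,
    CnvCall,
    Interval,
    ValidationError,
    ploidy_map,
    sort_calls,
)
from .depth import NormalizedProfile, mask_bins

log = logging.getLogger(__name__)

_TOL = 1e-12


@dataclass
class Segment:
    """A maximal run of bins with homogeneous mean copy value."""

    interval: Interval
    n_bins: int
    mean: float
    p_value: Optional[float] = None  # permutation p of the split creating it


def _max_arc_stat(v: np.ndarray, min_bins: int):
    """Max circular arc statistic and its (leftmost) arc for one segment.

    The statistic for arc [i, i+k) is |A - kT/n| / sqrt(k(n-k)), the
    two-sample t numerator under a fixed within-segment variance; the
    variance term is permutation-invariant so it cancels from the test.
    Ties resolve to the smallest start, then the shortest arc.
    """
    n = len(v)
    S = np.empty(n + 1)
    S[0] = 0.0
    np.cumsum(v, out=S[1:])
    T = S[-1]
    best = 0.0
    bi, bk = None, None
    for k in range(min_bins, n - min_bins + 1):
        arc = S[k:] - S[: n - k + 1]
        z = np.abs(arc - k * T / n) / math.sqrt(k * (n - k))
        j = int(np.argmax(z))
        m = float(z[j])
        if m > best + _TOL or (
            abs(m - best) <= _TOL and bi is not None and j < bi
        ):
            best, bi, bk = m, j, k
    return best, bi, bk


def _max_arc_stat_batch(P: np.ndarray, min_bins: int) -> np.ndarray:
    """Max arc statistic per row for a batch of permuted segments."""
    m, n = P.shape
    S = np.zeros((m, n + 1))
    np.cumsum(P, axis=1, out=S[:, 1:])
    T = S[:, -1:]
    best = np.zeros(m)
    for k in range(min_bins, n - min_bins + 1):
        arc = S[:, k:] - S[:, : n - k + 1]
        z = np.abs(arc - (k / n) * T)
        np.maximum(best, z.max(axis=1) / math.sqrt(k * (n - k)), out=best)
    return best


def _split_pvalue(v, obs, min_bins, n_permutations, alpha, rng, chunk=128):
    """Permutation p-value of the observed max arc statistic.

    Permutations run in chunks with sequential early stopping: once the
    exceedance count guarantees p >= alpha no further permutations can
    change the accept/reject decision, so the test returns early with a
    conservative p. Ties count as exceedances.
    """
    stop_count = math.ceil(alpha * (n_permutations + 1) - 1)
    count, done = 0, 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        P = rng.permuted(np.broadcast_to(v, (b, len(v))), axis=1)
        stats = _max_arc_stat_batch(P, min_bins)
        count += int(np.count_nonzero(stats >= obs - _TOL))
        done += b
        if count >= stop_count:
            break
    return (1 + count) / (1 + done)


def _segment_values(v, alpha, n_permutations, min_bins, rng):
    """Recursive CBS on one value array; yields (lo, hi, p) in order."""
    out = []

    def rec(lo, hi, pval):
        n = hi - lo
        if n >= 2 * min_bins:
            obs, bi, bk = _max_arc_stat(v[lo:hi], min_bins)
            if bi is not None and obs > _TOL:
                p = _split_pvalue(v[lo:hi], obs, min_bins, n_permutations,
                                  alpha, rng)
                if p < alpha:
                    cuts = sorted({lo, lo + bi, lo + bi + bk, hi})
                    for a, b in zip(cuts[:-1], cuts[1:]):
                        rec(a, b, p)
                    return
        out.append((lo, hi, pval))

    rec(0, len(v), None)
    return out


def cbs_segment(nprof: NormalizedProfile, alpha: float = 0.01,
                n_permutations: int = 1000, min_bins: int = 2,
                seed: int = 0, mask: Sequence = ()) -> list:
    """Segment a normalized profile, one chromosome at a time.

    `mask` is the calling-time (centromere-minimal) gray list; bins
    overlapping it by more than half their length are removed before
    segmentation. Deterministic given the seed.
    """
    if n_permutations < 100:
        raise ValidationError(
            "n_permutations < 100 gives too coarse a p-value resolution"
        )
    if mask:
        nprof = mask_bins(nprof, mask)
    segments = []
    ss = np.random.SeedSequence(seed)
    for chrom, child in zip(nprof.chroms(), ss.spawn(len(nprof.chroms()))):
        cb = nprof.bins[chrom]
        if not len(cb):
            continue
        rng = np.random.default_rng(child)
        pieces = _segment_values(cb.values, alpha, n_permutations, min_bins, rng)
        for lo, hi, p in pieces:
            segments.append(Segment(
                interval=Interval(chrom, int(cb.starts[lo]), int(cb.ends[hi - 1])),
                n_bins=hi - lo,
                mean=float(np.mean(cb.values[lo:hi])),
                p_value=p,
            ))
    return segments


def _phred(p: Optional[float]) -> Optional[float]:
    if p is None:
        return None
    return min(99.0, -10.0 * math.log10(max(p, 1e-10)))


def segments_to_calls(segments: Sequence[Segment], ploidy: dict) -> list:
    """Round segment means to integer copy states and emit GAIN/LOSS calls.

    Segments whose rounded copy equals the expected ploidy are reference
    and dropped. A permutation-derived quality score is recorded for
    information but is never used as a filter.
    """
    calls = []
    for seg in segments:
        expected = ploidy[seg.interval.chrom]
        cn = max(0, int(math.floor(seg.mean + 0.5)))
        if cn == expected:
            continue
        calls.append(CnvCall(
            interval=seg.interval,
            type=GAIN if cn > expected else LOSS,
            copy_number=cn,
            depth_estimate=seg.mean,
            n_bins=seg.n_bins,
            quality=_phred(seg.p_value),
        ))
    return calls


def filter_min_support(calls: Sequence[CnvCall], min_bins: int = 8) -> list:
    """Drop candidate calls supported by fewer than `min_bins` depth bins."""
    kept = [c for c in calls if c.n_bins >= min_bins]
    log.info("min-support filter (>=%d bins): %d -> %d calls",
             min_bins, len(calls), len(kept))
    return kept


def merge_adjacent(calls: Sequence[CnvCall], max_gap: int = 100_000) -> list:
    """Merge same-chromosome, same-type, same-copy-state calls spaced by
    less than `max_gap` bases (strict inequality) into single calls.

    The gap magnitudes absorbed by each merge are recorded on the merged
    call for downstream curation. n_bins are summed and the depth
    estimate is the bin-weighted mean over the called segments only (the
    gap itself contributes nothing). Transitive left-to-right; idempotent.
    """
    by_chrom: dict = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    out = []
    for chrom in by_chrom:
        group = by_chrom[chrom]
        starts = [c.start for c in group]
        if starts != sorted(starts):
            raise ValidationError(f"calls on {chrom} are not sorted by start")
        cur = group[0]
        for nxt in group[1:]:
            gap = nxt.start - cur.end
            if (gap < max_gap and nxt.type == cur.type
                    and nxt.copy_number == cur.copy_number):
                nb = cur.n_bins + nxt.n_bins
                de = None
                if cur.depth_estimate is not None and nxt.depth_estimate is not None:
                    de = (cur.depth_estimate * cur.n_bins
                          + nxt.depth_estimate * nxt.n_bins) / nb
                q = None
                quals = [x for x in (cur.quality, nxt.quality) if x is not None]
                if quals:
                    q = max(quals)
                cur = cur.replace(
                    interval=Interval(chrom, cur.start, nxt.end),
                    n_bins=nb,
                    depth_estimate=de,
                    quality=q,
                    gap_lengths=cur.gap_lengths + (gap,) + nxt.gap_lengths,
                )
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    merged = sort_calls(out)
    if len(merged) != len(calls):
        log.info("adjacent-call merge (<%d bp): %d -> %d calls",
                 max_gap, len(calls), len(merged))
    return merged


def flag_mosaic(call: CnvCall, gain_threshold: float = 2.25,
                loss_threshold: float = 1.75) -> CnvCall:
    """Label a call putative-mosaic from its continuous depth estimate.

    Gains are flagged when the estimate falls below gain_threshold
    (default 2.25X: a constitutional single-copy gain should sit at 3X),
    losses when it rises above loss_threshold (default 1.75X: a
    constitutional heterozygous loss sits at 1X). Thresholds are anchored
    to the diploid scale and configurable.
    """
    if call.depth_estimate is None:
        return call
    if call.type == GAIN:
        return call.replace(mosaic_flag=call.depth_estimate < gain_threshold)
    return call.replace(mosaic_flag=call.depth_estimate > loss_threshold)


def estimate_purity(call: CnvCall, expected_ploidy: int = 2) -> float:
    """Carrier cell fraction under a linear mixture of diploid and CNV cells.

    purity = (depth_estimate - ploidy) / (copy_number - ploidy), clipped
    into (0, 1]. A constitutional event gives 1.0.
    """
    if call.copy_number == expected_ploidy:
        raise ValidationError("purity undefined when copy number equals ploidy")
    if call.depth_estimate is None:
        raise ValidationError("purity requires a depth estimate")
    p = (call.depth_estimate - expected_ploidy) / (call.copy_number - expected_ploidy)
    return float(min(1.0, max(1e-6, p)))


def call_cnvs(nprof: NormalizedProfile, calling_graylist: Sequence = (),
              alpha: float = 0.01, n_permutations: int = 1000,
              min_bins_per_segment: int = 2, min_support_bins: int = 8,
              merge_gap: int = 100_000, mosaic_gain_threshold: float = 2.25,
              mosaic_loss_threshold: float = 1.75, seed: int = 0) -> list:
    """Full caller: segment, call, support-filter, merge, flag, estimate.

    b-allele-based ploidy correction is deliberately absent (it costs
    false negatives); heterozygous-variant screening of deletions lives
    downstream as an advisory annotation instead.
    """
    segs = cbs_segment(nprof, alpha=alpha, n_permutations=n_permutations,
                       min_bins=min_bins_per_segment, seed=seed,
                       mask=calling_graylist)
    ploidy = ploidy_map(nprof.layout, nprof.sex)
    calls = segments_to_calls(segs, ploidy)
    log.info("segmentation produced %d segments, %d candidate calls",
             len(segs), len(calls))
    calls = filter_min_support(calls, min_support_bins)
    calls = merge_adjacent(calls, merge_gap)
    out = []
    for c in calls:
        c = flag_mosaic(c, mosaic_gain_threshold, mosaic_loss_threshold)
        exp = ploidy[c.chrom]
        if c.copy_number != exp:
            c = c.replace(purity=estimate_purity(c, exp))
        out.append(c)
    return out
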