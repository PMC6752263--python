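"""Call-set concordance and array-based confirmation statistics.

Sensitivity and replication are reference-anchored overlap matches (a
reference call is recovered when a same-type query call covers enough of
its span); array confirmation ranks a call's median probe intensity
against size-matched background windows drawn from chromosome 1, giving
an add-one empirical p-value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GAIN, LOSS, CnvCall, ValidationError


@dataclass
class MatchRecord:
    reference: CnvCall
    recovered: bool
    best_overlap: float
    matched_query: Optional[int]  # index into the query set


@dataclass
class MatchResult:
    """Pairing of a query call set against a reference set."""

    records: list
    query_matched: list  # bool per query call

    @property
    def sensitivity(self) -> float:
        if not self.records:
            return float("nan")
        return sum(r.recovered for r in self.records) / len(self.records)

    @property
    def recovered(self):
        return [r.reference for r in self.records if r.recovered]

    @property
    def missed(self):
        return [r.reference for r in self.records if not r.recovered]


def overlap_fraction(query: CnvCall, reference: CnvCall,
                     reciprocal: bool = False) -> float:
    """Fraction of the reference interval covered by the query.

    Reference-anchored by default ("overlap with reference call
    boundaries"); with reciprocal=True the minimum of both directions is
    used, the common benchmarking convention. Cross-chromosome pairs are 0.
    """
    inter = query.interval.intersection_length(reference.interval)
    frac_ref = inter / reference.interval.length
    if not reciprocal:
        return frac_ref
    return min(frac_ref, inter / query.interval.length)


def match_callsets(query: Sequence[CnvCall], reference: Sequence[CnvCall],
                   threshold: float = 0.5, require_same_type: bool = True,
                   reciprocal: bool = False) -> MatchResult:
    """Match each reference call to its best-overlapping query call.

    A reference call is recovered when some (same-type, if required)
    query call reaches the overlap threshold. One query may recover
    several fragmented reference calls; fragmentation is tolerated.
    """
    records = []
    matched = [False] * len(query)
    for ref in reference:
        best, best_i = 0.0, None
        for i, q in enumerate(query):
            if require_same_type and q.type != ref.type:
                continue
            f = overlap_fraction(q, ref, reciprocal=reciprocal)
            if f > best:
                best, best_i = f, i
        hit = best >= threshold and best > 0
        if hit:
            matched[best_i] = True
        records.append(MatchRecord(ref, hit, best, best_i if hit else None))
    return MatchResult(records, matched)


def replication_rate(callset_a: Sequence[CnvCall], callset_b: Sequence[CnvCall],
                     threshold: float = 0.75, **kw) -> float:
    """Directional fraction of callset A recovered in callset B."""
    if not callset_a:
        return float("nan")
    return match_callsets(callset_b, callset_a, threshold=threshold, **kw).sensitivity


@dataclass
class ConfirmationResult:
    evaluable: bool
    p_value: Optional[float]
    n_probes: int
    call_median: Optional[float] = None
    n_draws: int = 0


def confirmation_pvalue(call: CnvCall, probes: pd.DataFrame,
                        n_draws: int = 1000, min_probes: int = 4,
                        seed: int = 0,
                        background_chrom: str = "chr1") -> ConfirmationResult:
    """Empirical confirmation p for a call from array probe intensities.

    The call's median probe logR is ranked against medians of size-matched
    windows drawn uniformly over `background_chrom` (excluding windows
    overlapping the call itself); direction is one-sided: background
    medians <= the call's for a LOSS, >= for a GAIN. Add-one formula
    p = (1 + extreme) / (n + 1) keeps p > 0. Calls spanning fewer than
    `min_probes` probes are not evaluable.
    """
    bg = probes[probes["chrom"] == background_chrom]
    if bg.empty:
        raise ValidationError(f"no {background_chrom} probes for background")
    in_call = probes[
        (probes["chrom"] == call.chrom)
        & (probes["pos"] >= call.start) & (probes["pos"] < call.end)
    ]
    n_probes = len(in_call)
    if n_probes < min_probes:
        return ConfirmationResult(False, None, n_probes)
    call_median = float(in_call["logr"].median())
    pos = np.sort(bg["pos"].to_numpy())
    vals = bg.set_index("pos").loc[pos, "logr"].to_numpy()
    length = call.interval.length
    hi = int(pos[-1]) - length
    if hi <= int(pos[0]):
        raise ValidationError("background chromosome shorter than the call")
    rng = np.random.default_rng(seed)
    medians = []
    attempts = 0
    while len(medians) < n_draws:
        attempts += 1
        if attempts > 50 * n_draws:
            raise ValidationError("could not place background windows")
        s = int(rng.integers(int(pos[0]), hi))
        if call.chrom == background_chrom and not (
            s + length <= call.start or s >= call.end
        ):
            continue
        i0, i1 = np.searchsorted(pos, [s, s + length])
        if i1 <= i0:
            continue
        medians.append(float(np.median(vals[i0:i1])))
    medians = np.asarray(medians)
    if call.type == LOSS:
        extreme = int(np.count_nonzero(medians <= call_median))
    else:
        extreme = int(np.count_nonzero(medians >= call_median))
    p = (1 + extreme) / (n_draws + 1)
    return ConfirmationResult(True, p, n_probes, call_median, n_draws)


def mcnemar_exact(n_discordant_a: int, n_discordant_b: int) -> float:
    """Exact McNemar p for paired recovery indicators.

    Inputs are the two discordant counts (recovered by A only / by B
    only); under the null of equal sensitivity they split Binomial(n,
    1/2), so the test is the exact two-sided binomial test.
    """
    n = n_discordant_a + n_discordant_b
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_discordant_a, n, 0.5).pvalue)


def paired_sensitivity_comparison(query_a, query_b, reference,
                                  threshold: float = 0.5, **kw):
    """Compare two call sets' sensitivity on one reference via McNemar.

    Returns (sensitivity_a, sensitivity_b, p_value) using paired per-
    reference recovery indicators.
    """
    ra = match_callsets(query_a, reference, threshold=threshold, **kw)
    rb = match_callsets(query_b, reference, threshold=threshold, **kw)
    a_only = sum(1 for x, y in zip(ra.records, rb.records)
                 if x.recovered and not y.recovered)
    b_only = sum(1 for x, y in zip(ra.records, rb.records)
                 if y.recovered and not x.recovered)
    return ra.sensitivity, rb.sensitivity, mcnemar_exact(a_only, b_only)
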