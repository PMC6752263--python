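"""Core domain types: genome layout, intervals, CNV calls, gray regions.

All coordinates are 0-based half-open (BED convention). VCF-like output
converts to 1-based inclusive at the I/O boundary only.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

GAIN = "GAIN"
LOSS = "LOSS"

GRAY_TIER_CALLING = "centromere-minimal"
GRAY_TIER_FULL = "full"


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


class NoCoverageError(ValidationError):
    """Raised when a query interval overlaps no depth bins / grid cells."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths and sex-chromosome labels.

    The reference assembly is abstracted away: any ordered set of named,
    positive-length sequences works, so tests run on kilobase-scale toy
    genomes while real use supplies hg19-style layouts.
    """

    lengths: tuple  # tuple of (name, length) pairs, order = genome order
    sex_chromosomes: frozenset = frozenset({"chrX", "chrY"})

    def __post_init__(self):
        names = [n for n, _ in self.lengths]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for n, ln in self.lengths:
            if ln <= 0:
                raise ValidationError(f"non-positive length for {n}: {ln}")
        object.__setattr__(self, "_index", {n: ln for n, ln in self.lengths})

    @classmethod
    def from_dict(cls, lengths, sex_chromosomes=("chrX", "chrY")):
        return cls(tuple(lengths.items()), frozenset(sex_chromosomes))

    @property
    def names(self):
        return tuple(n for n, _ in self.lengths)

    @property
    def autosomes(self):
        return tuple(n for n in self.names if n not in self.sex_chromosomes)

    def __contains__(self, chrom):
        return chrom in self._index

    def length(self, chrom) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def is_autosome(self, chrom) -> bool:
        self.length(chrom)
        return chrom not in self.sex_chromosomes

    def validate_interval(self, interval: "Interval") -> None:
        ln = self.length(interval.chrom)
        if interval.end > ln:
            raise ValidationError(
                f"interval {interval} extends past end of "
                f"{interval.chrom} (length {ln})"
            )


def ploidy_map(layout: GenomeLayout, sex: str) -> dict:
    """Expected integer copy per chromosome: 2 for autosomes; X/Y by sex.

    Any sex chromosome not named chrX/chrY is treated as X-like (2 in
    females, 1 in males) unless its name ends in 'Y'.
    """
    if sex not in ("male", "female"):
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    out = {}
    for chrom in layout.names:
        if layout.is_autosome(chrom):
            out[chrom] = 2
        elif chrom.endswith("Y"):
            out[chrom] = 1 if sex == "male" else 0
        else:
            out[chrom] = 1 if sex == "male" else 2
    return out


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __str__(self):
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.intersection_length(other) > 0

    def intersection_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "Interval") -> Optional[int]:
        """Distance between closest edges; 0 for any overlap or abutment.

        None for intervals on different chromosomes (distance undefined).
        """
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def merge_intervals(intervals: Iterable[Interval]) -> list:
    """Union of intervals as a sorted list of disjoint intervals."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


def intersection_with_union(interval: Interval, regions: Iterable[Interval]) -> int:
    """Bases of `interval` covered by the union of `regions`."""
    return sum(interval.intersection_length(m) for m in merge_intervals(regions))


@dataclass(frozen=True)
class GrayRegion:
    """A region of unreliable depth signal.

    tier 'centromere-minimal' is masked before segmentation; tier 'full'
    (the complete problem-region + common-CNV list) is applied as a
    post-calling filter.
    """

    interval: Interval
    tier: str = GRAY_TIER_FULL

    def __post_init__(self):
        if self.tier not in (GRAY_TIER_CALLING, GRAY_TIER_FULL):
            raise ValidationError(f"unknown gray-list tier {self.tier!r}")


@dataclass
class CnvCall:
    """A contiguous GAIN/LOSS interval with copy state and annotation slots.

    depth_estimate is the continuous copy-number estimate on the diploid
    scale (2.0 = diploid); copy_number is its integer call. Annotation
    fields are filled progressively by the filtering stages.
    """

    interval: Interval
    type: str
    copy_number: int
    depth_estimate: Optional[float] = None
    n_bins: int = 1
    quality: Optional[float] = None  # permutation-p-derived, never a filter
    mosaic_flag: bool = False
    purity: Optional[float] = None
    gap_lengths: tuple = ()  # gaps absorbed by adjacent-call merging
    genes: tuple = ()
    population_frequency: Optional[float] = None
    graylist_fraction: Optional[float] = None
    het_count: Optional[int] = None
    inheritance: Optional[str] = None

    def __post_init__(self):
        if self.type not in (GAIN, LOSS):
            raise ValidationError(f"call type must be GAIN or LOSS, got {self.type!r}")
        if self.copy_number < 0:
            raise ValidationError("copy_number must be non-negative")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if self.population_frequency is not None and not (
            0.0 <= self.population_frequency <= 1.0
        ):
            raise ValidationError("population_frequency must lie in [0, 1]")

    @property
    def chrom(self):
        return self.interval.chrom

    @property
    def start(self):
        return self.interval.start

    @property
    def end(self):
        return self.interval.end

    def replace(self, **kw) -> "CnvCall":
        return dataclasses.replace(self, **kw)


def sort_calls(calls: Sequence[CnvCall], layout: Optional[GenomeLayout] = None):
    """Sort calls genome order (layout order when given, else name order)."""
    if layout is None:
        return sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    rank = {n: i for i, n in enumerate(layout.names)}
    return sorted(calls, key=lambda c: (rank.get(c.chrom, len(rank)), c.start, c.end))
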