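"""Post-calling annotation and heuristic filtering.

Three filters run in fixed order — gray-list overlap, gene proximity,
panel population frequency — with per-stage counts logged, plus an
advisory heterozygous-variant screen for candidate deletions. The order
and every cutoff are the clinical pipeline's interpretation-burden
heuristics, config-exposed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GAIN,
    LOSS,
    CnvCall,
    GenomeLayout,
    Interval,
    ValidationError,
    intersection_with_union,
    ploidy_map,
)
from .depth import GriddedProfile, covered_fraction, mean_copy

log = logging.getLogger(__name__)


@dataclass
class PopulationPanel:
    """Reference cohort of gridded depth summaries, queryable by interval.

    All samples share one fixed-width grid; the manifest records each
    sample's sex so sex-chromosome queries can be restricted to same-sex
    samples.
    """

    layout: GenomeLayout
    grid_width: int
    profiles: dict  # sample_id -> GriddedProfile
    sexes: dict  # sample_id -> "male" | "female"

    def __post_init__(self):
        if not self.profiles:
            raise ValidationError("panel must contain at least one sample")
        missing = set(self.profiles) - set(self.sexes)
        if missing:
            raise ValidationError(f"manifest missing samples: {sorted(missing)}")
        for sid, prof in self.profiles.items():
            if prof.grid_width != self.grid_width:
                raise ValidationError(f"sample {sid} is on a different grid")

    @property
    def n(self):
        return len(self.profiles)


def graylist_overlap(call: CnvCall, gray_regions: Sequence) -> float:
    """Fraction of a call's span covered by the union of gray regions."""
    ivs = [r.interval if hasattr(r, "interval") else r for r in gray_regions]
    if not ivs:
        return 0.0
    covered = intersection_with_union(call.interval, ivs)
    return covered / call.interval.length


def filter_graylist(calls: Sequence[CnvCall], gray_regions: Sequence,
                    threshold: float = 0.5) -> list:
    """Remove calls with more than `threshold` of their range gray-listed.

    Strictly greater-than: a call exactly half covered survives. Every
    surviving call carries its overlap fraction as an annotation.
    """
    kept = []
    for c in calls:
        frac = graylist_overlap(c, gray_regions)
        if frac <= threshold:
            kept.append(c.replace(graylist_fraction=frac))
    log.info("gray-list filter (> %.0f%% overlap removed): %d -> %d calls",
             100 * threshold, len(calls), len(kept))
    return kept


def annotate_genes(calls: Sequence[CnvCall], genes: Sequence,
                   proximity: int = 5_000) -> list:
    """Attach overlapping or nearby (< proximity bp) genes; drop calls with
    no gene-proximal annotation.

    Distance is between closest interval edges (0 for any overlap); the
    inequality is strict, so a gene exactly `proximity` away does not
    rescue a call. Gene lists are sorted for determinism.
    """
    kept = []
    for c in calls:
        hit = set()
        for iv, name in genes:
            gap = c.interval.gap_to(iv)
            if gap is not None and gap < proximity:
                hit.add(name or str(iv))
        if hit:
            kept.append(c.replace(genes=tuple(sorted(hit))))
    log.info("gene-proximity filter (< %d bp): %d -> %d calls",
             proximity, len(calls), len(kept))
    return kept


def population_frequency(call: CnvCall, panel: PopulationPanel,
                         proband_sex: Optional[str] = None,
                         loss_threshold: float = 1.75,
                         gain_threshold: float = 2.25,
                         min_interval_covered: float = 0.5) -> float:
    """Fraction of eligible panel samples whose depth over the call
    interval is consistent with the proband's GAIN/LOSS status.

    The three-step heuristic: (1) pull the panel's gridded depth over the
    call boundaries, (2) take each sample's length-weighted mean, (3)
    count samples below the loss threshold (LOSS) or above the gain
    threshold (GAIN). On sex chromosomes only same-sex samples are
    eligible, and thresholds scale by expected-ploidy/2 so a haploid-X
    male is judged against ~1X, not 2X. Samples with less than
    `min_interval_covered` of the interval on non-missing cells are
    excluded from the denominator.
    """
    chrom = call.chrom
    on_sex = not panel.layout.is_autosome(chrom)
    if on_sex and proband_sex is None:
        raise ValidationError("sex-chromosome query requires the proband sex")
    eligible, consistent = 0, 0
    for sid, prof in panel.profiles.items():
        sex = panel.sexes[sid]
        if on_sex and sex != proband_sex:
            continue
        if covered_fraction(prof, call.interval) < min_interval_covered:
            log.debug("panel sample %s excluded: interval under-covered", sid)
            continue
        expected = ploidy_map(panel.layout, sex)[chrom]
        if expected == 0:
            continue
        scale = expected / 2.0
        m = mean_copy(prof, call.interval)
        eligible += 1
        if call.type == LOSS and m < loss_threshold * scale:
            consistent += 1
        elif call.type == GAIN and m > gain_threshold * scale:
            consistent += 1
    if eligible == 0:
        raise ValidationError(f"no eligible panel samples for {call.interval}")
    return consistent / eligible


def filter_population(calls: Sequence[CnvCall], max_frequency: float = 0.10) -> list:
    """Remove calls with annotated population frequency strictly above
    `max_frequency` (default 10%, ~5% allele frequency)."""
    for c in calls:
        if c.population_frequency is None:
            raise ValidationError("population frequency not annotated")
    kept = [c for c in calls if c.population_frequency <= max_frequency]
    log.info("population-frequency filter (> %.0f%% removed): %d -> %d calls",
             100 * max_frequency, len(calls), len(kept))
    return kept


def annotate_population(calls: Sequence[CnvCall], panel: PopulationPanel,
                        proband_sex: Optional[str] = None, **kw) -> list:
    return [
        c.replace(population_frequency=population_frequency(
            c, panel, proband_sex=proband_sex, **kw))
        for c in calls
    ]


_HET = {"0/1", "1/0", "0|1", "1|0"}


def het_screen(call: CnvCall, variants) -> CnvCall:
    """Count heterozygous proband genotypes inside a candidate deletion.

    A copy-number <= 1 region should carry no heterozygous calls; any
    present raise an advisory flag (recorded as het_count) for manual
    curation. Never removes the call.
    """
    if call.type != LOSS or call.copy_number > 1:
        raise ValidationError("het screen applies to deletions with copy <= 1")
    if isinstance(variants, pd.DataFrame):
        rows = variants[["chrom", "pos", "gt"]].itertuples(index=False)
    else:
        rows = ((call.chrom, pos, gt) for pos, gt in variants)
    count = sum(
        1 for chrom, pos, gt in rows
        if chrom == call.chrom and call.interval.contains(int(pos)) and gt in _HET
    )
    if count:
        log.info("deletion %s carries %d heterozygous variants (advisory)",
                 call.interval, count)
    return call.replace(het_count=count)
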