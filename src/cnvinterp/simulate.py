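"""Synthetic inputs for every pipeline stage.

Emulates the uniform depth of PCR-free genome sequencing: per-bin read
counts are negative binomial (overdispersed Poisson) around a mean scaled
by the local expected copy number, with implanted germline or mosaic CNV
events. Also generates frequency-structured reference panels, Mendelian
trio SNV genotypes consistent with hemizygous deletions or duplications,
and size-matched array probe intensities.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import PopulationPanel
from .core import (
    GAIN,
    LOSS,
    CnvCall,
    GenomeLayout,
    Interval,
    ValidationError,
    ploidy_map,
)
from .depth import ChromBins, DepthProfile, normalize, to_grid
from .phase import MATERNAL, PATERNAL, TrioGenotypes, TrioSite


@dataclass(frozen=True)
class SimulatedCnvSpec:
    """A CNV to implant: interval, true integer copy, mosaic cell fraction.

    mosaic_fraction 1.0 is a constitutional event; the effective expected
    copy is ploidy + fraction * (copy_number - ploidy).
    """

    interval: Interval
    copy_number: int
    mosaic_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.mosaic_fraction <= 1.0:
            raise ValidationError("mosaic_fraction must lie in (0, 1]")
        if self.copy_number < 0:
            raise ValidationError("copy_number must be non-negative")

    def expected_copy(self, ploidy: float = 2.0) -> float:
        ec = ploidy + self.mosaic_fraction * (self.copy_number - ploidy)
        if ec <= 0:
            raise ValidationError("expected copy must be positive")
        return ec


@dataclass
class PanelSpec:
    """A reference cohort to simulate: sample sexes plus (variant,
    population frequency) pairs carried independently across samples."""

    sexes: Sequence[str]
    variants: Sequence[tuple] = ()  # (SimulatedCnvSpec, frequency)

    def __post_init__(self):
        if len(self.sexes) < 1:
            raise ValidationError("panel needs at least one sample")
        for _, f in self.variants:
            if not 0.0 <= f <= 1.0:
                raise ValidationError("variant frequency must lie in [0, 1]")


def _check_disjoint(specs):
    by_chrom: dict = {}
    for s in specs:
        by_chrom.setdefault(s.interval.chrom, []).append(s.interval)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(ivs[:-1], ivs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping CNV specs on {chrom}: {a} vs {b}"
                )


def simulate_depth_profile(layout: GenomeLayout,
                           cnv_specs: Sequence[SimulatedCnvSpec] = (),
                           mean_reads_per_bin: float = 100.0,
                           dispersion: float = 0.1,
                           bin_width: int = 1_000,
                           seed: int = 0,
                           sample_id: str = "sim",
                           sex: str = "female"):
    """Simulate a binned depth profile with implanted CNVs.

    Per-bin counts are NB with mean mean_reads_per_bin * expected_copy/2
    and variance m + dispersion * m^2 (dispersion 0 falls back to
    Poisson). Returns (DepthProfile, truth call list); truth calls carry
    the implanted expected copy as their depth estimate.
    """
    if mean_reads_per_bin <= 0:
        raise ValidationError("mean reads per bin must be positive")
    if dispersion < 0:
        raise ValidationError("dispersion must be non-negative")
    _check_disjoint(cnv_specs)
    rng = np.random.default_rng(seed)
    ploidy = ploidy_map(layout, sex)
    bins = {}
    for chrom in layout.names:
        clen = layout.length(chrom)
        starts = np.arange(0, clen, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, clen)
        base = float(ploidy[chrom])
        expected = np.full(len(starts), base)
        widths = (ends - starts).astype(float)
        for spec in cnv_specs:
            if spec.interval.chrom != chrom:
                continue
            lo = np.maximum(starts, spec.interval.start)
            hi = np.minimum(ends, spec.interval.end)
            w = np.maximum(0, hi - lo) / widths
            ec = spec.expected_copy(base if base > 0 else 2.0)
            expected = expected * (1 - w) + ec * w
        mean = mean_reads_per_bin * (ends - starts) / bin_width * expected / 2.0
        counts = np.zeros(len(starts))
        pos = mean > 0
        if dispersion > 0:
            r = 1.0 / dispersion
            p = r / (r + mean[pos])
            counts[pos] = rng.negative_binomial(r, p)
        else:
            counts[pos] = rng.poisson(mean[pos])
        bins[chrom] = ChromBins(starts, ends, counts)
    profile = DepthProfile(layout, bins, sample_id=sample_id, sex=sex)
    truth = []
    for spec in cnv_specs:
        base = float(ploidy[spec.interval.chrom])
        base = base if base > 0 else 2.0
        cb = bins[spec.interval.chrom]
        mids = (cb.starts + cb.ends) // 2
        nb = int(np.sum((mids >= spec.interval.start) & (mids < spec.interval.end)))
        truth.append(CnvCall(
            interval=spec.interval,
            type=GAIN if spec.copy_number > base else LOSS,
            copy_number=spec.copy_number,
            depth_estimate=spec.expected_copy(base),
            n_bins=max(1, nb),
            mosaic_flag=spec.mosaic_fraction < 1.0,
            purity=spec.mosaic_fraction,
        ))
    return profile, truth


def simulate_panel(layout: GenomeLayout, panel_spec: PanelSpec, seed: int = 0,
                   grid_width: int = 300, **depth_kwargs):
    """Simulate a reference panel of gridded, normalized depth summaries.

    Each sample carries each variant independently with its stated
    frequency (an unrelated cohort). Returns (PopulationPanel, realized
    carrier counts per variant index).
    """
    rng = np.random.default_rng(seed)
    profiles, sexes = {}, {}
    realized = {i: 0 for i in range(len(panel_spec.variants))}
    child_seeds = np.random.SeedSequence(seed).spawn(len(panel_spec.sexes))
    for i, (sex, child) in enumerate(zip(panel_spec.sexes, child_seeds)):
        sid = f"panel{i:04d}"
        carried = []
        for vi, (spec, freq) in enumerate(panel_spec.variants):
            if rng.random() < freq:
                carried.append(spec)
                realized[vi] += 1
        prof, _ = simulate_depth_profile(
            layout, carried, seed=child, sample_id=sid, sex=sex, **depth_kwargs
        )
        profiles[sid] = to_grid(normalize(prof), grid_width)
        sexes[sid] = sex
    panel = PopulationPanel(layout=layout, grid_width=grid_width,
                            profiles=profiles, sexes=sexes)
    return panel, realized


def _hw_genotype(rng, af):
    alleles = (rng.random(2) < af).astype(int)
    return alleles


def _gt_str(alleles):
    return "/".join(str(a) for a in sorted(alleles))


def simulate_trio_region(n_snvs: int, allele_frequency: float,
                         proband_cn: int, origin: str, seed: int = 0,
                         error_rate: float = 0.0,
                         interval: Optional[Interval] = None,
                         spacing: int = 100) -> TrioGenotypes:
    """Simulate trio SNV genotypes inside a proband CNV region.

    Parents are Hardy-Weinberg at the stated allele frequency; each
    transmits one haplotype. For copy number 1 the haplotype from the
    origin parent is deleted, leaving the other parent's transmitted
    allele as the proband's haploid observation; for copy number 3 an
    extra independent draw from the origin parent is added. With
    error_rate 0 the observations are Mendelian-consistent by
    construction; a positive rate replaces each observation with a
    uniform state that often.
    """
    if n_snvs < 1:
        raise ValidationError("need at least one SNV site")
    if proband_cn not in (1, 3):
        raise ValidationError("proband copy number must be 1 or 3")
    if origin not in (MATERNAL, PATERNAL):
        raise ValidationError(f"unknown parent-of-origin {origin!r}")
    rng = np.random.default_rng(seed)
    start = interval.start if interval is not None else 0
    sites = []
    for i in range(n_snvs):
        mom = _hw_genotype(rng, allele_frequency)
        dad = _hw_genotype(rng, allele_frequency)
        m_t = mom[rng.integers(2)]
        f_t = dad[rng.integers(2)]
        if proband_cn == 1:
            obs = int(m_t if origin == PATERNAL else f_t)
            k = 2
        else:
            extra_parent = mom if origin == MATERNAL else dad
            extra = extra_parent[rng.integers(2)]
            obs = int(m_t + f_t + extra)
            k = 4
        if error_rate > 0 and rng.random() < error_rate:
            obs = int(rng.integers(k))
        sites.append(TrioSite(pos=start + spacing * (i + 1),
                              gt_mother=_gt_str(mom), gt_father=_gt_str(dad),
                              proband_obs=obs))
    return TrioGenotypes(sites=sites, copy_number=proband_cn, interval=interval)


def simulate_probe_intensities(layout: GenomeLayout, spacing: int = 1_000,
                               cnv_specs: Sequence[SimulatedCnvSpec] = (),
                               noise_sd: float = 0.2,
                               seed: int = 0) -> pd.DataFrame:
    """Size-matched array probe intensities: logR = log2(copy/2) + noise.

    Probes sit at spacing/2 + k*spacing on every chromosome; a diploid
    region has mean logR 0. Returns a chrom/pos/logr table.
    """
    if spacing <= 0:
        raise ValidationError("probe spacing must be positive")
    _check_disjoint(cnv_specs)
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in layout.names:
        clen = layout.length(chrom)
        pos = np.arange(spacing // 2, clen, spacing, dtype=np.int64)
        copy = np.full(len(pos), 2.0)
        for spec in cnv_specs:
            if spec.interval.chrom != chrom:
                continue
            inside = (pos >= spec.interval.start) & (pos < spec.interval.end)
            copy[inside] = spec.expected_copy(2.0)
        logr = np.log2(copy / 2.0) + rng.normal(0.0, noise_sd, len(pos))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "logr": logr}))
    return pd.concat(frames, ignore_index=True)


def trio_to_dataframe(trio: TrioGenotypes, chrom: str = "chr1") -> pd.DataFrame:
    """Flatten TrioGenotypes to the trio-table TSV schema."""
    c = trio.interval.chrom if trio.interval is not None else chrom
    return pd.DataFrame({
        "chrom": c,
        "pos": [s.pos for s in trio.sites],
        "gt_mother": [s.gt_mother for s in trio.sites],
        "gt_father": [s.gt_father for s in trio.sites],
        "proband_obs": [s.proband_obs for s in trio.sites],
    })
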