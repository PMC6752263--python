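"""Parental origin of CNVs.

Two complementary routes: (1) depth — if one parent carries the same
dosage change over the call interval, the event is inherited from that
parent; (2) likelihood-based phasing from trio SNV genotypes for de novo
events (and duos), which asks on which parental haplotype the event arose.

The SNV model constructs, per site, a prior over the proband's observable
allele state given the parental genotypes, the proband's copy number in
the region, and an inheritance assumption; site likelihoods multiply and
the most likely assumption wins, with a conservative ambiguity margin.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GAIN, LOSS, CnvCall, Interval, ValidationError
from .depth import NormalizedProfile, mean_copy

MATERNAL = "maternal"
PATERNAL = "paternal"
ASSUMPTIONS = (MATERNAL, PATERNAL)

_DOSE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2,
         "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}


def _dose(gt: str) -> Optional[int]:
    """ALT-allele dose of a diploid genotype string; None when missing."""
    if gt is None or gt in (".", "./.", ".|."):
        return None
    try:
        return _DOSE[gt]
    except KeyError:
        raise ValidationError(f"unrecognized genotype {gt!r}") from None


@dataclass(frozen=True)
class TrioSite:
    """One SNV site inside the CNV region.

    proband_obs is the ALT-allele count of the proband's observation:
    0/1 for a haploid (copy-number-1) region, 0..3 for a triploid one.
    """

    pos: int
    gt_mother: str
    gt_father: str
    proband_obs: int


@dataclass
class TrioGenotypes:
    """SNV sites with mother/father/proband observations in one CNV region."""

    sites: list
    copy_number: Optional[int] = None
    interval: Optional[Interval] = None


@dataclass
class InheritanceResult:
    """Ranked inheritance assumptions for one CNV."""

    log_likelihood: dict  # assumption -> float
    selected: Optional[str]
    ambiguous: bool
    n_informative: int
    per_site: list = field(default_factory=list)

    @property
    def log_likelihood_ratio(self) -> float:
        a, b = (self.log_likelihood[k] for k in ASSUMPTIONS)
        return a - b


def _bern_convolve(ps):
    """Distribution of a sum of independent Bernoulli(p) draws."""
    dist = np.array([1.0])
    for p in ps:
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def site_prior(gt_mother: str, gt_father: str, copy_number: int,
               assumption: str) -> np.ndarray:
    """Prior over proband allele states at one site under one assumption.

    copy number 1 (deletion): the assumption names the parent whose
    haplotype is deleted; the proband's single allele is a uniform draw
    from the *other* parent's two alleles. Returns P over ALT count
    {0, 1}. Worked single-site case, mother 0/1 x father 0/0: a paternal
    deletion gives REF/ALT each 50%; a maternal deletion gives REF 100%,
    ALT 0%.

    copy number 3 (duplication): the proband carries one transmitted
    allele from each parent plus a second independent draw from the
    assumption parent; returns P over ALT count {0, 1, 2, 3}.
    """
    if assumption not in ASSUMPTIONS:
        raise ValidationError(f"unknown assumption {assumption!r}")
    dm, df = _dose(gt_mother), _dose(gt_father)
    if dm is None or df is None:
        raise ValidationError("site_prior requires both parental genotypes")
    if copy_number == 1:
        surviving = dm if assumption == PATERNAL else df
        p_alt = surviving / 2.0
        return np.array([1.0 - p_alt, p_alt])
    if copy_number == 3:
        extra = dm if assumption == MATERNAL else df
        return _bern_convolve([dm / 2.0, df / 2.0, extra / 2.0])
    raise ValidationError(f"unsupported copy number {copy_number} (need 1 or 3)")


def n_states(copy_number: int) -> int:
    return 2 if copy_number == 1 else 4


def is_informative(gt_mother: str, gt_father: str, copy_number: int) -> bool:
    """A site is informative when the two assumptions predict different
    observation distributions (requires valid parental genotypes)."""
    try:
        pm = site_prior(gt_mother, gt_father, copy_number, MATERNAL)
        pp = site_prior(gt_mother, gt_father, copy_number, PATERNAL)
    except ValidationError:
        return False
    return bool(np.max(np.abs(pm - pp)) > 1e-12)


def phase_denovo_cnv(trio: TrioGenotypes, copy_number: Optional[int] = None,
                     error_rate: float = 0.01,
                     margin: float = 2.0) -> InheritanceResult:
    """Select the most likely parental-origin assumption across all SNVs.

    Per-site likelihood is the mixture (1 - eps) * prior(obs) + eps *
    uniform; the genotype-error term eps keeps a single discordant site
    from zeroing a model (eps = 0 reproduces the exact textbook priors).
    Sites with missing parental genotypes are skipped, never imputed. The
    result is ambiguous when no informative site exists or the
    log-likelihood gap is below `margin` nats.
    """
    if not trio.sites:
        raise ValidationError("phasing requires at least one SNV site")
    if not 0.0 <= error_rate <= 0.1:
        raise ValidationError("error_rate must lie in [0, 0.1]")
    cn = copy_number if copy_number is not None else trio.copy_number
    if cn not in (1, 3):
        raise ValidationError(f"unsupported copy number {cn} (need 1 or 3)")
    k = n_states(cn)
    ll = {a: 0.0 for a in ASSUMPTIONS}
    per_site = []
    n_inf = 0
    for site in trio.sites:
        if _dose(site.gt_mother) is None or _dose(site.gt_father) is None:
            continue
        if not 0 <= site.proband_obs < k:
            raise ValidationError(
                f"proband observation {site.proband_obs} out of range for cn {cn}"
            )
        if is_informative(site.gt_mother, site.gt_father, cn):
            n_inf += 1
        contrib = {}
        for a in ASSUMPTIONS:
            prior = site_prior(site.gt_mother, site.gt_father, cn, a)
            lik = (1.0 - error_rate) * prior[site.proband_obs] + error_rate / k
            contrib[a] = math.log(lik) if lik > 0 else -math.inf
            ll[a] += contrib[a]
        per_site.append((site.pos, contrib))
    ranked = sorted(ASSUMPTIONS, key=lambda a: ll[a], reverse=True)
    best, second = ll[ranked[0]], ll[ranked[1]]
    gap = best - second
    ambiguous = (n_inf == 0) or not math.isfinite(best) or gap < margin
    selected = None if (n_inf == 0 or not math.isfinite(best)) else ranked[0]
    return InheritanceResult(log_likelihood=ll, selected=selected,
                             ambiguous=ambiguous, n_informative=n_inf,
                             per_site=per_site)


DE_NOVO = "de novo"
BIPARENTAL = "biparental/ambiguous"
NOT_ASSESSABLE = "not assessable by depth"


def inheritance_by_depth(call: CnvCall,
                         mother: Optional[NormalizedProfile] = None,
                         father: Optional[NormalizedProfile] = None,
                         loss_threshold: float = 1.75,
                         gain_threshold: float = 2.25) -> str:
    """Classify inheritance by genotyping parental dosage over the call.

    A parent is a carrier when its mean copy over the interval deviates
    from its expected ploidy in the call's direction beyond the mosaic
    thresholds (scaled by ploidy/2 on sex chromosomes). No carrier means
    de novo; one carrier names the parent; both is ambiguous. With a
    missing parent the call is not assessable by depth and the SNV-based
    phasing is the fallback.
    """
    if mother is None or father is None:
        return NOT_ASSESSABLE
    carriers = []
    for label, prof, sex in ((MATERNAL, mother, "female"),
                             (PATERNAL, father, "male")):
        from .core import ploidy_map  # late import keeps module load cheap

        expected = ploidy_map(prof.layout, sex)[call.chrom]
        if expected == 0:
            continue
        scale = expected / 2.0
        m = mean_copy(prof, call.interval)
        if call.type == LOSS and m < loss_threshold * scale:
            carriers.append(label)
        elif call.type == GAIN and m > gain_threshold * scale:
            carriers.append(label)
    if not carriers:
        return DE_NOVO
    if len(carriers) == 1:
        return carriers[0]
    return BIPARENTAL


def trio_from_dataframe(df, interval: Optional[Interval] = None,
                        copy_number: Optional[int] = None) -> TrioGenotypes:
    """Build TrioGenotypes from a table with chrom/pos/gt_mother/gt_father/
    proband_obs columns, optionally restricted to one interval."""
    sites = []
    for row in df.itertuples(index=False):
        if interval is not None:
            if row.chrom != interval.chrom or not interval.contains(int(row.pos)):
                continue
        sites.append(TrioSite(int(row.pos), str(row.gt_mother),
                              str(row.gt_father), int(row.proband_obs)))
    return TrioGenotypes(sites=sites, copy_number=copy_number, interval=interval)
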