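# Methods

This note documents the models implemented in `cnvinterp`, the defaults
and why they are set where they are, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Depth model and normalization

The unit of analysis is the depth bin: a window sized so a fixed expected
number of reads (`depth.expected_reads_per_bin`, default 100) map inside
it at diploid state. `make_bins` derives a fixed bin width from the
genome-wide mean per-base read count; it does not attempt mappability-
aware variable-width binning — problem regions are handled by the gray
list instead, which keeps the binning free of external annotation tracks.

Normalization is strictly per-sample: `value_i = 2 · density_i /
median(autosomal densities)`. The median is used rather than the mean so
that large CNVs and whole-chromosome aneuploidies do not drag the
constant; sex chromosomes share the autosomal constant so a 46,XY male
reads ≈ 1.0 on X. Two quantified caveats, both visible in the test
suite's design:

- **Aneuploid mass.** The median is only anchored while diploid bins form
  a clear majority. A trisomy spanning ~30% of analyzed bins moves the
  median ~0.5 σ of bin noise into the diploid distribution; at ~5% of the
  genome (a real chr14 is ~4% of hg19) the shift is negligible. Toy
  genomes in tests are proportioned accordingly.
- **Count skew.** Negative-binomial counts are right-skewed, so the
  median sits below the mean; at dispersion 0.1 (variance = m + 0.1 m²,
  CV ≈ 33%) the gap is ~3.5% and every normalized value inflates by that
  factor. Real PCR-free genomes are far less dispersed (CV ≈ 10–15%,
  dispersion ≈ 0.01), where the skew is immaterial. Purity-recovery tests
  therefore run at dispersion 0.01; segmentation-power tests deliberately
  run at the much harsher 0.1.

For the population panel, normalized profiles are resampled onto a fixed
300-bp grid (`depth.grid_width_bp`) by length-weighted averaging; cells
with no source data are missing (NaN), never zero, and propagate as
missing through interval means.

## Segmentation and calling

`cbs_segment` implements circular binary segmentation: for a segment of
n bins, the statistic for the arc [i, i+k) is |A − kT/n| / √(k(n−k))
(the two-sample t numerator under a fixed within-segment variance — the
variance term is permutation-invariant and cancels from the test). The
observed maximum over all arcs is compared against the permutation null;
the split is accepted at p < α. Defaults: α = 0.01, 1,000 permutations,
minimum arm 2 bins (`segment.*`). Numerical choices:

- Ties in the arc maximum resolve to the smallest start then the shortest
  arc; segmentation is deterministic given the seed (one child seed per
  chromosome).
- The permutation loop stops early once the exceedance count guarantees
  p ≥ α; this cannot change any accept/reject decision, only the runtime.
- Ties between permuted and observed statistics count as exceedances, so
  constant segments (all-equal values) are never split.
- The calling-time gray list (centromere-minimal tier) is masked before
  segmentation: bins overlapping it by more than half their length are
  dropped. The full gray list is applied only after calling.

Segment means round half-up to integer copy states against the expected
ploidy (2 on autosomes; X/Y by sex). Reference segments are dropped;
GAIN/LOSS calls keep the unrounded depth estimate. Candidate calls need
≥ 8 supporting bins (`segment.min_support_bins`; the deliberately lowered
support threshold trades specificity for sensitivity in the 10–50 kb
range), and same-chromosome/type/state calls separated by gaps < 100 kb
merge into one call with the gap magnitudes recorded for curation. The
merged depth estimate is the bin-weighted mean over called segments only;
the gap contributes nothing (the merged event's interior state is a
curation question, not a statistical one). A permutation-derived quality
score is recorded per call but is intentionally never a filter, and no
b-allele-based ploidy correction is applied — heterozygous-variant
screening of deletions is a downstream advisory annotation instead.

**Mosaic labeling.** Gains are flagged putative-mosaic when the depth
estimate falls below 2.25X, losses when above 1.75X. The source
convention pairing "1.75X and 2.25X … for gains and losses, respectively"
is inconsistent with dosage arithmetic (a sub-constitutional *gain* lies
below 3X, approaching 2X from above); this package pairs 2.25 with gains
and 1.75 with losses, and both thresholds are configurable
(`segment.mosaic_gain_threshold` / `segment.mosaic_loss_threshold`).
Purity is the linear mixture estimate (depth − ploidy)/(CN − ploidy),
clipped into (0, 1]. Note one knife-edge: a 50% mosaic single-copy gain
has expected depth exactly 2.5, which integer rounding sends to CN 2 or
CN 3 on noise — detection of exactly-half mosaics is intrinsically
unstable in an integer-state caller. The thresholds are anchored to the
diploid scale; on sex chromosomes they are meaningful only after scaling
(see filtering).

## Filtering and annotation

Filters run in a fixed order — gray list, gene proximity, population
frequency — and each logs in/out counts; `run_case` records them in the
`CaseSummary` so the interpretation burden of a case is auditable.

- **Gray list:** calls with strictly more than 50% of their span covered
  by the *union* of gray regions are removed.
- **Genes:** a call keeps genes whose edge-to-edge distance is strictly
  under 5 kb (0 for any overlap); calls with no gene-proximal annotation
  are removed. The 5-kb margin absorbs boundary uncertainty and nearby
  promoters.
- **Population frequency:** the three-step heuristic — pull the panel's
  gridded depth over the call boundaries, take each eligible sample's
  length-weighted mean, count samples consistent with the call direction
  — then remove calls with frequency strictly above 10% (≈ 5% allele
  frequency under rare-carrier assumptions; occurrence frequency is
  reported, no per-sample genotype inference is attempted).
  "Consistent" reuses the mosaic thresholds (mean < 1.75 for LOSS,
  > 2.25 for GAIN) scaled by expected-ploidy/2, so a chrX query against
  males tests against ≈ 0.875/1.125 rather than diploid-scale values. On
  sex chromosomes only same-sex samples are eligible. Samples with less
  than half the interval on non-missing grid cells leave the denominator
  (logged). These consistency thresholds are the pipeline's most
  consequential free parameter: with a noisy panel they set the false-
  carrier rate, so short intervals (≲ 30 bins at dispersion 0.1) can
  accumulate spurious carriers. They are config-exposed
  (`annotate.{loss,gain}_consistency_threshold`).

## Phasing

Depth route: a parent whose mean copy over the call interval deviates
from its expected ploidy in the call's direction beyond the (scaled)
mosaic thresholds is a carrier; no carrier ⇒ de novo, one ⇒ that parent,
both ⇒ ambiguous, missing parent ⇒ not assessable (SNV fallback).

SNV route (`phase_denovo_cnv`): per site, a prior over the proband's
observable allele state given parental genotypes, region copy number and
a parental-origin assumption. For CN 1 the origin parent's haplotype is
deleted and the proband's single allele is a uniform draw from the other
parent's two alleles. For CN 3 the proband carries one transmitted allele
per parent plus a second *independent* draw from the origin parent; the
distribution is over ALT counts {0..3}. The independent-draw model is a
deliberate simplification — the duplicated haplotype is in reality the
transmitted one, but at unlinked single sites the two models coincide,
and without allele-balance observations the duplicated-genotype states
collapse onto observable counts anyway (a lossy mapping, documented
here). Per-site likelihood is (1−ε)·prior + ε·uniform with ε default 0.01
(`phase.error_rate`), which keeps one genotyping error from zeroing a
model; ε = 0 reproduces the exact closed-form priors. Sites with missing
parental genotypes are skipped, never imputed. The decision is declared
ambiguous when no informative site exists or the log-likelihood gap is
under 2 nats (`phase.ambiguity_margin_nats`) — a conservative,
clinical-style margin. Mosaic-aware phasing likelihoods are out of scope.

## Evaluation

Overlap is reference-anchored (fraction of the reference call covered),
with a symmetric reciprocal mode behind a flag; matching tolerates
fragmentation (one query may recover several reference calls) and
requires type agreement by default. Replication is the directional
recovery fraction at 75% overlap. Paired sensitivity comparisons use the
exact McNemar test (two-sided binomial on discordant pairs).

Array confirmation draws size-matched windows uniformly over chromosome 1
(excluding windows overlapping the call when the call is on chr1),
computes each window's median probe logR, and reports the add-one
empirical p = (1 + #as-or-more-extreme)/(n + 1), one-sided in the call's
direction. Calls spanning fewer than 4 probes are not evaluable. The
background draw count defaults to 1,000 (`evaluate.n_background_draws`);
the add-one pseudo-count keeps p > 0.

## Digital karyogram

Depth bins surviving the variable-position mask (midpoint assignment,
> 50%-overlap exclusion) are grouped into 100-kb segments; each segment's
histogram over copy-value bins (0–4 in 0.1 steps, config-exposed) becomes
a heatmap column, so column mass equals the number of contributing bins.
B-allele fractions follow the same protocol in 500-kb segments. Because a
curated population-variable-position mask is external data, the package
can derive a synthetic stand-in from a simulated panel
(`variance_mask_from_panel`: grid cells above a variance quantile).

## Synthetic study conditions

The generator emulates what matters to a depth-based caller: per-bin
negative-binomial counts (overdispersion configurable; 0.1 by default in
the generator, deliberately harsher than real PCR-free data) scaled by
the local expected copy `ploidy + f·(CN − ploidy)`; independent carriers
in panels (an unrelated cohort); Hardy–Weinberg parents with faithful
transmission plus the region's dosage change; probe logR = log2(copy/2)
plus Gaussian noise. It does not emulate GC bias, mappability structure,
read-level artifacts, breakpoint hotspots, or relatedness — so passing
tests demonstrate the statistical machinery under honest noise, not
robustness to alignment artifacts (that is what the gray list is for in
real deployments).

Problem sizes used by the simulation-backed acceptance tests, chosen once
as realistic desk-scale analogues: segmentation power over 200 replicates
of a 400-bin chromosome with one implanted 25-bin loss or 30-bin gain at
dispersion 0.1; purity recovery at fractions 0.3/0.5/0.7 on a 1,000-bin
mosaic chromosome inside a 20,000-bin genome at dispersion 0.01; phasing
recovery over 1,000 trio regions with ≥ 10 informative sites at ε = 0.01;
panel-frequency recovery on a 60-sample panel with implanted frequencies
0.05/0.20/0.40; empirical-p calibration over 500 neutral 20-kb calls with
a fresh probe table per call (so p-values are independent); replication
over three pairs of independent noise replicates of a four-event truth
set. Events queried against the panel are ≥ 50 bins so sample means sit
well clear of the consistency thresholds.

## Known limitations

- Mosaic flagging thresholds are diploid-anchored; on male sex
  chromosomes the caller reports haploid-relative states correctly but
  mosaic labels there should not be trusted without rescaling.
- The caller emits integer copy states; exactly-half mosaics round
  unstably (see above).
- The population-frequency heuristic counts directional dosage shifts,
  not genotypes; it cannot distinguish a common CNV from a recurrently
  noisy region.
- CBS p-values are conditional on the recursion path (no multiple-testing
  correction across splits), as in standard practice; α controls
  per-split, not genome-wide, error.
- The CN 3 phasing model ignores allele balance; with it, power would be
  higher for duplications.
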