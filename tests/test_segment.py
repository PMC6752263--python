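"""CBS segmentation, call formation, merging, mosaic labeling, purity."""
import numpy as np
import pytest

from cnvinterp.core import CnvCall, GenomeLayout, Interval, ValidationError
from cnvinterp.depth import normalize
from cnvinterp.evaluate import match_callsets
from cnvinterp.segment import (
    call_cnvs,
    cbs_segment,
    estimate_purity,
    filter_min_support,
    flag_mosaic,
    merge_adjacent,
    segments_to_calls,
    Segment,
)
from cnvinterp.simulate import SimulatedCnvSpec, simulate_depth_profile

from conftest import make_normalized


def _loss(start, end, cn=1, n_bins=20, depth=None, chrom="chr1"):
    return CnvCall(Interval(chrom, start, end), "LOSS", cn,
                   depth_estimate=depth, n_bins=n_bins)


class TestCbs:
    def test_noiseless_step_breakpoint_exact(self, layout):
        vals = np.concatenate([np.full(250, 2.0), np.full(250, 1.0)])
        n = make_normalized(layout, {"chr1": vals})
        segs = cbs_segment(n, seed=0)
        assert len(segs) == 2
        assert segs[0].interval == Interval("chr1", 0, 250_000)
        assert segs[1].interval == Interval("chr1", 250_000, 500_000)
        assert segs[0].mean == pytest.approx(2.0)
        assert segs[1].mean == pytest.approx(1.0)

    def test_type_one_error_controlled_on_null_profiles(self, layout):
        """A constant-mean noisy profile stays one segment in >=95% of
        replicates at alpha 0.01."""
        single = 0
        reps = 50
        for rep in range(reps):
            prof, _ = simulate_depth_profile(
                GenomeLayout.from_dict({"chr1": 500_000}), seed=1000 + rep)
            segs = cbs_segment(normalize(prof), seed=rep)
            single += len(segs) == 1
        assert single >= int(0.95 * reps) - 1  # one-replicate slack on 50

    def test_implanted_loss_recovered(self, layout):
        """20-bin heterozygous losses in overdispersed noise are found
        with >=50% overlap in nearly every replicate."""
        hits = 0
        reps = 20
        iv = Interval("chr1", 200_000, 220_000)
        for rep in range(reps):
            prof, truth = simulate_depth_profile(
                GenomeLayout.from_dict({"chr1": 500_000}),
                [SimulatedCnvSpec(iv, 1)], seed=2000 + rep)
            calls = call_cnvs(normalize(prof), seed=rep)
            res = match_callsets(calls, truth, threshold=0.5)
            hits += res.sensitivity == 1.0
        assert hits >= reps - 1

    def test_seed_determinism(self, layout):
        prof, _ = simulate_depth_profile(
            GenomeLayout.from_dict({"chr1": 400_000}),
            [SimulatedCnvSpec(Interval("chr1", 100_000, 130_000), 3)], seed=5)
        n = normalize(prof)
        a = cbs_segment(n, seed=9)
        b = cbs_segment(n, seed=9)
        assert [(s.interval, s.mean) for s in a] == [(s.interval, s.mean) for s in b]

    def test_low_permutation_count_rejected(self, make_profile):
        n = make_profile({"chr1": np.full(20, 2.0)})
        with pytest.raises(ValidationError):
            cbs_segment(n, n_permutations=50)

    def test_calling_mask_excludes_bins(self, layout):
        vals = np.full(100, 2.0)
        vals[40:60] = 0.1  # a centromere-like hole
        n = make_normalized(layout, {"chr1": vals})
        segs = cbs_segment(n, mask=[Interval("chr1", 40_000, 60_000)], seed=0)
        assert len(segs) == 1  # masked bins never reach the segmenter


class TestSegmentsToCalls:
    PLOIDY = {"chr1": 2}

    def _seg(self, mean, n_bins=20):
        return Segment(Interval("chr1", 0, 1000 * n_bins), n_bins, mean)

    @pytest.mark.parametrize("mean,expected", [
        (0.98, ("LOSS", 1)),
        (3.6, ("GAIN", 4)),
        (0.2, ("LOSS", 0)),
    ])
    def test_rounding_to_copy_state(self, mean, expected):
        (c,) = segments_to_calls([self._seg(mean)], self.PLOIDY)
        assert (c.type, c.copy_number) == expected
        assert c.depth_estimate == pytest.approx(mean)  # unrounded retained

    def test_reference_segments_dropped(self):
        assert segments_to_calls([self._seg(2.04)], self.PLOIDY) == []

    def test_male_x_hemizygous_is_reference(self):
        seg = Segment(Interval("chrX", 0, 20_000), 20, 1.02)
        assert segments_to_calls([seg], {"chrX": 1}) == []


class TestMinSupport:
    def test_boundary_at_eight_bins(self):
        calls = [_loss(0, 7_000, n_bins=7), _loss(10_000, 18_000, n_bins=8)]
        kept = filter_min_support(calls)
        assert [c.n_bins for c in kept] == [8]

    def test_empty_input(self):
        assert filter_min_support([]) == []


class TestMerge:
    def test_sub_100kb_gap_merged_with_gap_recorded(self):
        a = _loss(100_000, 200_000, depth=1.1, n_bins=100)
        b = _loss(250_000, 300_000, depth=0.9, n_bins=50)
        (m,) = merge_adjacent([a, b])
        assert m.interval == Interval("chr1", 100_000, 300_000)
        assert m.n_bins == 150
        assert m.gap_lengths == (50_000,)
        # bin-weighted over called segments only
        assert m.depth_estimate == pytest.approx((1.1 * 100 + 0.9 * 50) / 150)

    def test_gap_of_exactly_100kb_not_merged(self):
        a = _loss(100_000, 200_000)
        b = _loss(300_000, 350_000)
        assert len(merge_adjacent([a, b])) == 2

    def test_copy_state_mismatch_not_merged(self):
        a = _loss(100_000, 200_000, cn=1)
        b = _loss(210_000, 250_000, cn=0)
        assert len(merge_adjacent([a, b])) == 2

    def test_never_merges_across_chromosomes(self):
        a = _loss(100_000, 200_000, chrom="chr1")
        b = _loss(210_000, 250_000, chrom="chr2")
        assert len(merge_adjacent([a, b])) == 2

    def test_transitive_and_idempotent(self):
        calls = [_loss(0, 50_000), _loss(60_000, 100_000), _loss(110_000, 150_000)]
        once = merge_adjacent(calls)
        assert len(once) == 1 and once[0].interval.end == 150_000
        assert once[0].gap_lengths == (10_000, 10_000)
        assert merge_adjacent(once) == once

    def test_output_never_longer_than_input(self):
        rng = np.random.default_rng(0)
        calls = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(1_000, 200_000))
            end = pos + int(rng.integers(8_000, 50_000))
            calls.append(_loss(pos, end))
            pos = end
        assert len(merge_adjacent(calls)) <= len(calls)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValidationError):
            merge_adjacent([_loss(200_000, 250_000), _loss(0, 100_000)])


class TestMosaicFlag:
    @pytest.mark.parametrize("type_,depth,flagged", [
        ("GAIN", 2.10, True),    # sub-constitutional gain
        ("GAIN", 2.90, False),   # constitutional single-copy gain
        ("LOSS", 1.80, True),    # shallow loss
        ("LOSS", 1.00, False),   # constitutional het loss
    ])
    def test_threshold_rule(self, type_, depth, flagged):
        cn = 3 if type_ == "GAIN" else 1
        c = CnvCall(Interval("chr1", 0, 10_000), type_, cn,
                    depth_estimate=depth, n_bins=10)
        assert flag_mosaic(c).mosaic_flag is flagged


class TestPurity:
    def test_linear_mixture(self):
        c = CnvCall(Interval("chr1", 0, 10_000), "GAIN", 3,
                    depth_estimate=2.5, n_bins=10)
        assert estimate_purity(c) == pytest.approx(0.5)

    def test_constitutional_loss_is_one(self):
        c = _loss(0, 10_000, depth=1.0)
        assert estimate_purity(c) == pytest.approx(1.0)

    def test_overshoot_clipped_to_one(self):
        c = CnvCall(Interval("chr1", 0, 10_000), "GAIN", 3,
                    depth_estimate=3.2, n_bins=10)
        assert estimate_purity(c) == 1.0

    def test_reference_copy_rejected(self):
        c = CnvCall(Interval("chr1", 0, 10_000), "GAIN", 3,
                    depth_estimate=2.5, n_bins=10)
        with pytest.raises(ValidationError):
            estimate_purity(c.replace(copy_number=2), expected_ploidy=2)
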