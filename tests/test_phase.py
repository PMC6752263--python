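"""Parental-origin inference: site priors, likelihood phasing, depth route."""
import itertools
import math

import numpy as np
import pytest

from cnvinterp.core import CnvCall, Interval, ValidationError
from cnvinterp.phase import (
    BIPARENTAL,
    DE_NOVO,
    MATERNAL,
    NOT_ASSESSABLE,
    PATERNAL,
    TrioGenotypes,
    TrioSite,
    inheritance_by_depth,
    phase_denovo_cnv,
    site_prior,
)
from cnvinterp.simulate import simulate_trio_region

from conftest import make_normalized

GTS = ["0/0", "0/1", "1/1"]
_ALLELES = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1)}


def brute_force_prior(gt_mother, gt_father, cn, assumption):
    """Enumerate every parental allele transmission explicitly."""
    mom, dad = _ALLELES[gt_mother], _ALLELES[gt_father]
    counts = {}
    if cn == 1:
        source = mom if assumption == PATERNAL else dad
        for a in source:
            counts[a] = counts.get(a, 0) + 1
        total = len(source)
        return np.array([counts.get(k, 0) / total for k in range(2)])
    # cn 3: one transmission from each parent plus an extra draw from the
    # origin parent, all combinations equally likely
    extra_src = mom if assumption == MATERNAL else dad
    combos = list(itertools.product(mom, dad, extra_src))
    for m, f, e in combos:
        counts[m + f + e] = counts.get(m + f + e, 0) + 1
    return np.array([counts.get(k, 0) / len(combos) for k in range(4)])


class TestSitePrior:
    def test_worked_single_site_case(self):
        """Mother 0/1, father 0/0, haploid proband: a paternal deletion
        leaves REF/ALT at 50%/50%; a maternal one at 100%/0%."""
        pat = site_prior("0/1", "0/0", 1, PATERNAL)
        mat = site_prior("0/1", "0/0", 1, MATERNAL)
        assert pat[0] == 0.5 and pat[1] == 0.5
        assert mat[0] == 1.0 and mat[1] == 0.0

    def test_duplication_from_homozygous_parents(self):
        """Mother 1/1 x father 0/0, extra copy paternal: exactly one ALT."""
        prior = site_prior("1/1", "0/0", 3, PATERNAL)
        assert np.array_equal(prior, [0.0, 1.0, 0.0, 0.0])

    @pytest.mark.parametrize("cn", [1, 3])
    @pytest.mark.parametrize("assumption", [MATERNAL, PATERNAL])
    def test_distributions_sum_to_one_exhaustively(self, cn, assumption):
        for gm in GTS:
            for gf in GTS:
                p = site_prior(gm, gf, cn, assumption)
                assert p.sum() == pytest.approx(1.0)
                assert np.all(p >= 0)

    @pytest.mark.parametrize("cn", [1, 3])
    @pytest.mark.parametrize("assumption", [MATERNAL, PATERNAL])
    def test_matches_transmission_enumeration_oracle(self, cn, assumption):
        for gm in GTS:
            for gf in GTS:
                got = site_prior(gm, gf, cn, assumption)
                want = brute_force_prior(gm, gf, cn, assumption)
                assert np.allclose(got, want), (gm, gf, cn, assumption)

    def test_unsupported_copy_number(self):
        with pytest.raises(ValidationError):
            site_prior("0/1", "0/0", 2, MATERNAL)


class TestPhaseDenovo:
    def _trio(self, sites, cn=1):
        return TrioGenotypes(sites=sites, copy_number=cn)

    def test_ten_concordant_sites_closed_form(self):
        """Ten mother-0/1 x father-0/0 sites all observed REF: the
        maternal-deletion model beats the paternal one by 10 ln 2 nats."""
        sites = [TrioSite(i, "0/1", "0/0", 0) for i in range(10)]
        res = phase_denovo_cnv(self._trio(sites), error_rate=0.0)
        assert res.selected == MATERNAL and not res.ambiguous
        assert res.log_likelihood[MATERNAL] == pytest.approx(0.0)
        assert res.log_likelihood_ratio == pytest.approx(10 * math.log(2))

    def test_single_alt_site_with_error_floor(self):
        """One ALT observation at a mother-0/1 x father-0/0 site: the
        maternal model survives only on the error term, so paternal wins."""
        res = phase_denovo_cnv(
            self._trio([TrioSite(0, "0/1", "0/0", 1)]), error_rate=0.01)
        assert res.log_likelihood[PATERNAL] > res.log_likelihood[MATERNAL]
        expected_gap = math.log(0.99 * 0.5 + 0.005) - math.log(0.005)
        gap = res.log_likelihood[PATERNAL] - res.log_likelihood[MATERNAL]
        assert gap == pytest.approx(expected_gap)

    def test_uninformative_sites_are_ambiguous(self):
        sites = [TrioSite(i, "0/0", "0/0", 0) for i in range(5)]
        res = phase_denovo_cnv(self._trio(sites), error_rate=0.0)
        assert res.ambiguous and res.selected is None
        assert res.n_informative == 0

    def test_margin_forces_ambiguity(self):
        sites = [TrioSite(0, "0/1", "0/0", 0)]  # single ln2 of evidence
        res = phase_denovo_cnv(self._trio(sites), error_rate=0.0, margin=2.0)
        assert res.ambiguous and res.selected == MATERNAL

    def test_missing_parent_genotypes_skipped(self):
        sites = [TrioSite(0, "./.", "0/0", 0),
                 TrioSite(1, "0/1", "0/0", 0)]
        res = phase_denovo_cnv(self._trio(sites), error_rate=0.0)
        assert res.n_informative == 1

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            phase_denovo_cnv(self._trio([]))

    def test_mother_father_swap_symmetry(self):
        """Swapping parental labels mirrors the selected model."""
        rng = np.random.default_rng(3)
        gts = [(GTS[rng.integers(3)], GTS[rng.integers(3)]) for _ in range(12)]
        obs = [int(rng.integers(2)) for _ in range(12)]
        fwd = phase_denovo_cnv(self._trio(
            [TrioSite(i, m, f, o) for i, ((m, f), o) in enumerate(zip(gts, obs))]))
        rev = phase_denovo_cnv(self._trio(
            [TrioSite(i, f, m, o) for i, ((m, f), o) in enumerate(zip(gts, obs))]))
        assert fwd.log_likelihood[MATERNAL] == pytest.approx(
            rev.log_likelihood[PATERNAL])
        assert fwd.log_likelihood[PATERNAL] == pytest.approx(
            rev.log_likelihood[MATERNAL])

    @pytest.mark.parametrize("cn", [1, 3])
    @pytest.mark.parametrize("origin", [MATERNAL, PATERNAL])
    def test_recovers_simulated_origin(self, cn, origin):
        trio = simulate_trio_region(30, 0.5, cn, origin, seed=42)
        res = phase_denovo_cnv(trio, error_rate=0.01)
        assert res.selected == origin


class TestInheritanceByDepth:
    def _profiles(self, layout, mother_copy, father_copy):
        mom = make_normalized(layout, {"chr1": np.full(100, mother_copy)},
                              sex="female")
        dad = make_normalized(layout, {"chr1": np.full(100, father_copy)},
                              sex="male")
        return mom, dad

    CALL = CnvCall(Interval("chr1", 20_000, 60_000), "LOSS", 1,
                   depth_estimate=1.0, n_bins=40)

    def test_carrier_parent_identified(self, layout):
        mom, dad = self._profiles(layout, 1.02, 2.01)
        assert inheritance_by_depth(self.CALL, mom, dad) == MATERNAL

    def test_no_carrier_is_de_novo(self, layout):
        mom, dad = self._profiles(layout, 2.0, 2.0)
        assert inheritance_by_depth(self.CALL, mom, dad) == DE_NOVO

    def test_both_carriers_ambiguous(self, layout):
        mom, dad = self._profiles(layout, 1.0, 1.0)
        assert inheritance_by_depth(self.CALL, mom, dad) == BIPARENTAL

    def test_missing_parent_degrades(self, layout):
        mom, _ = self._profiles(layout, 2.0, 2.0)
        assert inheritance_by_depth(self.CALL, mom, None) == NOT_ASSESSABLE
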