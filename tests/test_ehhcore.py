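"""EHHS/iES/Rsb statistics: pair-counting oracles and invariances."""

import itertools

import numpy as np
import pytest

from rsbscan import (
    ScanParams, ehhs_profile, haplotype_homozygosity, integrate_ies,
    prsb_transform, rsb_scan,
)

from conftest import make_panel


def brute_force_homozygosity(block):
    """All-pairs identity count divided by n(n-1)/2 ... expressed on the
    same n(n-1) scale as the implementation."""
    n = block.shape[0]
    same = sum(np.array_equal(block[i], block[j])
               for i, j in itertools.combinations(range(n), 2))
    return 2 * same / (n * (n - 1))


class TestHaplotypeHomozygosity:
    def test_identical_haplotypes(self):
        p = make_panel(np.zeros((4, 3)))
        assert haplotype_homozygosity(p, (0, 2)) == 1.0

    def test_all_distinct(self):
        p = make_panel([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert haplotype_homozygosity(p, (0, 1)) == 0.0

    def test_groups_2_1_1(self):
        p = make_panel([[0, 0], [0, 0], [1, 1], [1, 0]])
        assert haplotype_homozygosity(p, (0, 1)) == pytest.approx(1 / 6)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 11)) * 2
            m = int(rng.integers(1, 8))
            p = make_panel(rng.integers(0, 2, size=(n, m)))
            lo = int(rng.integers(0, m))
            hi = int(rng.integers(lo, m))
            got = haplotype_homozygosity(p, (lo, hi))
            want = brute_force_homozygosity(p.alleles[:, lo:hi + 1])
            assert got == pytest.approx(want)

    def test_empty_span_raises(self):
        p = make_panel([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            haplotype_homozygosity(p, (1, 0))


class TestEhhsProfile:
    def test_no_decay_sets_both_truncation_flags(self):
        # one allele path shared by half the haplotypes: EHHS stays at 1
        alleles = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]])
        prof = ehhs_profile(make_panel(alleles), focal=1, cutoff=0.05)
        assert prof.truncated_left and prof.truncated_right
        np.testing.assert_allclose(prof.ehhs, 1.0)

    def test_worked_four_haplotype_example(self):
        # haplotypes {00, 00, 11, 10}, focal SNP1: H(focal) = 1/3,
        # H(span 1-2) = 1/6, so EHHS at SNP2 = 0.5
        alleles = np.array([[0, 0], [0, 0], [1, 1], [1, 0]])
        prof = ehhs_profile(make_panel(alleles), focal=0, cutoff=0.05)
        k = list(prof.positions).index(make_panel(alleles).map.pos[1])
        assert prof.ehhs[k] == pytest.approx(0.5)

    def test_focal_value_is_one_and_nonincreasing_outward(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(2, 8)) * 2
            m = int(rng.integers(3, 15))
            alleles = rng.integers(0, 2, size=(n, m))
            focal = int(rng.integers(0, m))
            if alleles[:, focal].min() == alleles[:, focal].max():
                continue
            prof = ehhs_profile(make_panel(alleles), focal, cutoff=0.0)
            f = prof.focal_offset
            assert prof.ehhs[f] == 1.0
            right = prof.ehhs[f:]
            left = prof.ehhs[:f + 1][::-1]
            assert np.all(np.diff(right) <= 1e-12)
            assert np.all(np.diff(left) <= 1e-12)

    def test_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(4)
        alleles = rng.integers(0, 2, size=(8, 10))
        alleles[:4, 5] = 0
        alleles[4:, 5] = 1
        flipped = alleles.copy()
        flip_cols = [1, 5, 7]
        flipped[:, flip_cols] = 1 - flipped[:, flip_cols]
        p1 = ehhs_profile(make_panel(alleles), 5, cutoff=0.0)
        p2 = ehhs_profile(make_panel(flipped), 5, cutoff=0.0)
        np.testing.assert_allclose(p1.ehhs, p2.ehhs)

    def test_monomorphic_focal_raises(self):
        alleles = np.array([[0, 0], [0, 1], [0, 0], [0, 1]])
        with pytest.raises(ValueError):
            ehhs_profile(make_panel(alleles), focal=0)


class TestIntegrateIes:
    def test_two_trapezoids(self):
        from rsbscan.ehhcore import EhhsProfile
        prof = EhhsProfile(focal_index=1,
                           positions=np.array([0, 1000, 2000]),
                           ehhs=np.array([0.2, 1.0, 0.2]),
                           focal_offset=1)
        # two trapezoids of (1 + 0.2)/2 * 1000 each
        assert integrate_ies(prof, cutoff=0.25) == pytest.approx(1200.0)

    def test_single_snp_chromosome_is_missing_by_default(self):
        alleles = np.array([[0], [0], [1], [1]])
        prof = ehhs_profile(make_panel(alleles), 0)
        assert prof.truncated_left and prof.truncated_right
        assert integrate_ies(prof, discard_at_border=True) is None

    def test_all_one_profile_covers_chromosome_span(self):
        positions = np.array([1, 5001, 20001])
        alleles = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]])
        prof = ehhs_profile(make_panel(alleles, positions=positions), 1)
        assert integrate_ies(prof, discard_at_border=False) == \
            pytest.approx(20000.0)

    def test_invariant_to_points_beyond_cutoff_crossing(self):
        from rsbscan.ehhcore import EhhsProfile
        base = EhhsProfile(2, np.array([0., 500, 1000, 1500]),
                           np.array([0.01, 0.5, 1.0, 0.01]), 2)
        extended = EhhsProfile(2, np.array([-800., 0, 500, 1000, 1500, 2100]),
                               np.array([0.001, 0.01, 0.5, 1.0, 0.01, 0.0]), 3)
        assert integrate_ies(base, 0.05) == pytest.approx(
            integrate_ies(extended, 0.05))


class TestRsbScan:
    def test_identical_panels_give_zero_raw(self, neutral_replicates):
        p1, _, _ = neutral_replicates[0]
        res = rsb_scan(p1, p1)
        np.testing.assert_allclose(res.raw, 0.0)

    def test_standardization_is_exact(self, neutral_replicates):
        p1, p2, _ = neutral_replicates[0]
        res = rsb_scan(p1, p2)
        assert np.median(res.rsb_std) == pytest.approx(0.0, abs=1e-12)
        assert res.rsb_std.std() == pytest.approx(1.0)

    def test_mismatched_maps_raise(self, neutral_replicates):
        p1, p2, _ = neutral_replicates[0]
        q1, q2, _ = neutral_replicates[1]
        with pytest.raises(ValueError):
            rsb_scan(p1, q2)

    def test_sweep_signal_increases_with_selection_strength(
            self, neutral_replicates, sweep_replicates):
        """Mean rsb_std near the selected site is larger under s = 0.1
        than under s = 0 (monotonicity of the scan statistic in s at the
        extremes of the simulated range)."""
        def near_site_mean(reps):
            vals = []
            for p1, p2, truth in reps[:8]:
                res = rsb_scan(p1, p2)
                near = ((res.chrom == truth["selected_chrom"])
                        & (np.abs(res.pos - truth["selected_pos"])
                           <= 250_000))
                if near.any():
                    vals.append(res.rsb_std[near].mean())
            return np.mean(vals)

        assert near_site_mean(sweep_replicates) > \
            near_site_mean(neutral_replicates) + 0.25


class TestPrsbTransform:
    def test_zero_maps_to_log10_two(self):
        assert prsb_transform(0.0) == pytest.approx(np.log10(2), abs=1e-12)

    def test_upper_one_percent_quantile(self):
        assert prsb_transform(2.3263478740408408) == pytest.approx(2.0, abs=1e-9)

    def test_large_negative_scores_vanish(self):
        assert prsb_transform(-8.0) == pytest.approx(0.0, abs=1e-12)
        assert np.all(prsb_transform(np.linspace(-6, 6, 25)) >= 0)
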