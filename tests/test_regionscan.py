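"""Window construction, BH-FDR, and candidate-region calling."""

import itertools

import numpy as np
import pytest

from rsbscan import (
    CandidateRegion, bh_fdr, call_significant_regions,
    call_suggestive_regions, make_windows, merge_regions,
)
from rsbscan.ehhcore import RsbResult

from conftest import make_map


def fake_result(positions, prsb, q=None, chrom="1"):
    n = len(positions)
    return RsbResult(
        snp_index=np.arange(n), chrom=np.repeat(chrom, n),
        pos=np.asarray(positions), snp_id=np.array(
            [f"snp{i}" for i in range(n)], dtype=object),
        ies_sel=np.ones(n), ies_ref=np.ones(n), raw=np.zeros(n),
        rsb_std=np.zeros(n), prsb=np.asarray(prsb, dtype=float),
        q=None if q is None else np.asarray(q, dtype=float),
    )


class TestMakeWindows:
    def test_last_snp_at_2_6_mb_gives_6_windows(self):
        smap = make_map(27, spacing=100_000, start=1)  # last pos 2,600,001
        smap = make_map(27, spacing=100_000, start=0 + 1)
        smap.pos[-1] = 2_600_000
        wins = make_windows(smap, 1_000_000, 500_000)
        assert [w.start for w in wins] == [0, 500_000, 1_000_000,
                                           1_500_000, 2_000_000, 2_500_000]

    def test_last_snp_at_900kb_gives_2_windows(self):
        smap = make_map(10, spacing=100_000, start=1)
        smap.pos[-1] = 900_000
        wins = make_windows(smap, 1_000_000, 500_000)
        assert [w.start for w in wins] == [0, 500_000]

    def test_step_equals_width_tiles(self):
        smap = make_map(30, spacing=100_000, start=1)
        wins = make_windows(smap, 1_000_000, 1_000_000)
        starts = [w.start for w in wins]
        assert starts == sorted(set(starts))
        assert all(b - a == 1_000_000 for a, b in zip(starts, starts[1:]))

    def test_member_snps_assigned(self):
        smap = make_map(20, spacing=100_000, start=1)
        wins = make_windows(smap, 1_000_000, 500_000)
        for w in wins:
            for i in w.snp_indices:
                assert w.start <= smap.pos[i] - 1 < w.end

    def test_empty_map_raises(self):
        smap = make_map(1)
        with pytest.raises(ValueError):
            make_windows(smap.subset(np.array([], dtype=int)), 100, 100)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.05])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.05],
                                   rtol=1e-12)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 7), 0.2)

    def test_agrees_with_step_up_oracle_on_permutations(self):
        """Brute-force step-up definition q_(i) = min_{j>=i}(p_(j) m / j)
        over all permutations of 6 p-values."""
        base = [0.001, 0.008, 0.039, 0.041, 0.27, 0.9]

        def oracle(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                q[idx] = min(p[j] * m / (list(order).index(j) + 1)
                             for j in order[rank - 1:])
            return np.minimum(q, 1.0)

        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_fdr(list(perm)), oracle(perm),
                                       atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSuggestiveRegions:
    def test_needs_two_snps_above_threshold(self):
        smap = make_map(2, spacing=100_000, start=1)
        wins = make_windows(smap, 1_000_000, 500_000)
        res = fake_result(smap.pos, [2.5, 1.9])
        assert call_suggestive_regions(wins, res, 2.0, 2) == []
        res2 = fake_result(smap.pos, [2.5, 2.1])
        regs = call_suggestive_regions(wins, res2, 2.0, 2)
        assert len(regs) == 1 and regs[0].status == "suggestive"

    def test_threshold_is_strict(self):
        smap = make_map(2, spacing=1000, start=1)
        wins = make_windows(smap, 1_000_000, 500_000)
        res = fake_result(smap.pos, [2.0, 2.0])
        assert call_suggestive_regions(wins, res, 2.0, 2) == []

    def test_agrees_with_exhaustive_window_counting(self):
        """Random prsb vectors: flagged windows equal a brute-force
        per-window count before merging."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            positions = np.sort(rng.choice(
                np.arange(1, 3_000_000), size=n, replace=False))
            smap = make_map(n, spacing=1, start=1)
            smap.pos[:] = positions
            prsb = rng.exponential(1.0, size=n)
            wins = make_windows(smap, 1_000_000, 500_000)
            res = fake_result(positions, prsb)
            got = call_suggestive_regions(wins, res, 2.0, 2)
            flagged = []
            for w in wins:
                cnt = sum(1 for p, v in zip(positions, prsb)
                          if w.start <= p - 1 < w.end and v > 2.0)
                if cnt >= 2:
                    flagged.append((w.start, w.end))
            # every brute-force flagged window is inside a called region
            for s, e in flagged:
                assert any(r.start <= s and e <= r.end for r in got)
            # and every called region is a union of flagged windows
            total = sum(e - s for s, e in flagged)
            if not flagged:
                assert got == []


class TestSignificantRegions:
    def _region(self, qs):
        return CandidateRegion("1", 0, 1_000_000,
                               [(f"s{i}", 3.0, q) for i, q in enumerate(qs)],
                               "suggestive")

    def test_boundary_q_values(self):
        res = fake_result([1], [3.0], q=[0.01])
        assert call_significant_regions([self._region([0.04, 0.06])],
                                        res, 0.05) == []
        out = call_significant_regions([self._region([0.04, 0.045])],
                                       res, 0.05)
        assert len(out) == 1 and out[0].status == "significant"
        assert [m[0] for m in out[0].member_snps] == ["s0", "s1"]

    def test_empty_input(self):
        res = fake_result([1], [3.0], q=[0.01])
        assert call_significant_regions([], res, 0.05) == []


class TestMergeRegions:
    def r(self, start, end, ids=(), chrom="1"):
        return CandidateRegion(chrom, start, end,
                               [(i, 2.5, None) for i in ids], "suggestive")

    def test_half_overlap_union(self):
        out = merge_regions([self.r(9_000_000, 10_000_000),
                             self.r(9_500_000, 10_500_000)])
        assert [(x.start, x.end) for x in out] == [(9_000_000, 10_500_000)]

    def test_disjoint_unchanged(self):
        out = merge_regions([self.r(0, 1_000_000), self.r(2_000_000,
                                                          3_000_000)])
        assert len(out) == 2

    def test_chain_of_four_half_overlapping_windows(self):
        wins = [self.r(k * 500_000, k * 500_000 + 1_000_000)
                for k in range(4)]
        out = merge_regions(wins)
        assert [(x.start, x.end) for x in out] == [(0, 2_500_000)]

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(5)
        regs = [self.r(int(s), int(s) + int(rng.integers(1, 500_000)),
                       ids=(f"id{k}",))
                for k, s in enumerate(rng.integers(0, 5_000_000, size=15))]
        once = merge_regions(regs)
        twice = merge_regions(once)
        assert [(x.chrom, x.start, x.end) for x in once] == \
            [(x.chrom, x.start, x.end) for x in twice]
        shuffled = list(regs)
        rng.shuffle(shuffled)
        other = merge_regions(shuffled)
        assert [(x.start, x.end) for x in other] == \
            [(x.start, x.end) for x in once]

    def test_member_snps_deduplicated(self):
        out = merge_regions([self.r(0, 10, ids=("a", "b")),
                             self.r(5, 20, ids=("b", "c"))])
        assert [m[0] for m in out[0].member_snps] == ["a", "b", "c"]
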