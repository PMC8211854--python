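from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrkit.dmr import (DmrParams, call_windows, combine_lists, intersect_sets,
                        mask_dmrs, merge_adjacent, read_dmr_bed, window_test,
                        write_dmr_bed)
from dmrkit.intervals import GenomicInterval, tile_genome
from dmrkit.quant import RpkmMatrix, WindowCountMatrix, to_rpkm


def make_wcm(counts, libs=None, labels=None, ws=500):
    counts = np.asarray(counts)
    n = counts.shape[0]
    libs = np.asarray(libs if libs is not None else [1000] * counts.shape[1])
    labels = labels or ["A", "A", "B", "B"]
    win = tile_genome({"chr1": n * ws}, ws)
    return WindowCountMatrix(win, counts, libs, labels, ws)


def binom_two_sided_oracle(k, n, p0):
    """Independent enumeration with exact rational arithmetic (minlike)."""
    from math import comb
    p0 = Fraction(p0).limit_denominator(10**9)
    pmf = [comb(n, j) * p0**j * (1 - p0)**(n - j) for j in range(n + 1)]
    obs = pmf[k]
    return float(sum(q for q in pmf if q <= obs))


class TestWindowTest:
    def test_symmetric_null_p_one(self):
        wcm = make_wcm([[7, 7, 7, 7]])
        assert window_test(wcm, ("A", "B"), phi=0.0)[0] == 1.0

    def test_poisson_reduces_to_binomial(self):
        wcm = make_wcm([[15, 15, 3, 2]])
        p = window_test(wcm, ("A", "B"), phi=0.0)[0]
        assert p == pytest.approx(stats.binomtest(5, 35, 0.5).pvalue, rel=1e-9)
        assert p == pytest.approx(binom_two_sided_oracle(5, 35, 0.5), rel=1e-9)

    @pytest.mark.parametrize("sa,sb", [(10, 3), (25, 25), (0, 12), (40, 8)])
    def test_brute_force_oracle_equal_libs(self, sa, sb):
        counts = np.array([[sa // 2, sa - sa // 2, sb // 2, sb - sb // 2]])
        wcm = make_wcm(counts)
        p = window_test(wcm, ("A", "B"), phi=0.0)[0]
        assert p == pytest.approx(binom_two_sided_oracle(sb, sa + sb, 0.5), rel=1e-9)

    def test_unequal_lib_sizes_shift_null(self):
        # libs 3:1 -> expected split 1:3 of the total toward group A
        wcm = make_wcm([[15, 15, 5, 5]], libs=[1500, 1500, 500, 500])
        p = window_test(wcm, ("A", "B"), phi=0.0)[0]
        assert p == pytest.approx(stats.binomtest(10, 40, 0.25).pvalue, rel=1e-9)

    def test_zero_lib_rejected(self):
        wcm = make_wcm([[1, 1, 1, 1]], libs=[0, 0, 10, 10])
        with pytest.raises(ValueError, match="zero total library"):
            window_test(wcm, ("A", "B"), phi=0.0)

    def test_needs_two_reps(self):
        wcm = make_wcm([[1, 2]], libs=[10, 10], labels=["A", "B"])
        with pytest.raises(ValueError):
            window_test(wcm, ("A", "B"))

    def test_null_calibration(self):
        from dmrkit.quant import background_methylome
        from dmrkit.simulate import SimulationParams, make_genome, simulate_window_counts
        g = make_genome({"chr1": 5_000_000}, 1)
        params = SimulationParams(planted_fraction=0.0, dispersion=0.1,
                                  mean_rpkm=10, lib_sizes=(4_000_000,) * 16,
                                  seed=7)
        wcm, _ = simulate_window_counts(g, params)
        bg = background_methylome(to_rpkm(wcm))
        pv = window_test(wcm, ("A", "B"), background_mask=bg)
        rate = (pv < 0.01).mean()
        sd = np.sqrt(0.01 * 0.99 / len(pv))
        assert abs(rate - 0.01) < 3 * sd


class TestCallWindows:
    def make_rpkm(self, mean_a, mean_b, n=1):
        win = tile_genome({"chr1": 500 * n}, 500)
        arr = np.tile([[mean_a, mean_a, mean_b, mean_b]], (n, 1)).astype(float)
        return RpkmMatrix(win, arr, ["A", "A", "B", "B"])

    def test_fold_gate(self):
        rpkm = self.make_rpkm(10.0, 14.0)   # ratio ~1.4 < 1.5
        out = call_windows(rpkm, np.array([1e-6]), DmrParams(), ("A", "B"))
        assert len(out) == 0

    def test_hyper(self):
        rpkm = self.make_rpkm(10.0, 20.0)
        out = call_windows(rpkm, np.array([0.005]), DmrParams(), ("A", "B"))
        assert list(out["direction"]) == ["hyper"]

    def test_hypo(self):
        rpkm = self.make_rpkm(10.0, 5.0)
        out = call_windows(rpkm, np.array([0.005]), DmrParams(), ("A", "B"))
        assert list(out["direction"]) == ["hypo"]

    def test_p_gate(self):
        rpkm = self.make_rpkm(10.0, 20.0)
        out = call_windows(rpkm, np.array([0.02]), DmrParams(), ("A", "B"))
        assert len(out) == 0


def flagged_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fold", "p", "direction"])


class TestMergeAdjacent:
    def test_run_of_three(self):
        rows = [("chr1", 1500 + i * 500, 2000 + i * 500, 2.0, 0.001, "hyper")
                for i in range(3)]
        out = merge_adjacent(flagged_frame(rows))
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["end"] - rec["start"] == 1500 and rec["n_windows"] == 3

    def test_direction_split(self):
        rows = [("chr1", 0, 500, 2.0, 0.001, "hyper"),
                ("chr1", 500, 1000, 0.5, 0.001, "hypo")]
        out = merge_adjacent(flagged_frame(rows))
        assert len(out) == 2

    def test_isolated_singleton_kept(self):
        out = merge_adjacent(flagged_frame([("chr1", 0, 500, 2.0, 0.001, "hyper")]))
        assert len(out) == 1 and out.iloc[0]["end"] - out.iloc[0]["start"] == 500

    def test_singleton_dropped_in_strict_mode(self):
        out = merge_adjacent(flagged_frame([("chr1", 0, 500, 2.0, 0.001, "hyper")]),
                             DmrParams(drop_singletons=True))
        assert len(out) == 0

    def test_min_p_and_weighted_fold(self):
        rows = [("chr1", 0, 500, 2.0, 0.005, "hyper"),
                ("chr1", 500, 1000, 4.0, 0.001, "hyper")]
        rec = merge_adjacent(flagged_frame(rows)).iloc[0]
        assert rec["p"] == 0.001 and rec["fold"] == pytest.approx(3.0)

    def test_idempotent(self):
        rows = [("chr1", 500 * i, 500 * (i + 1), 2.0, 0.001, "hyper") for i in (0, 1, 5)]
        once = merge_adjacent(flagged_frame(rows))
        again = merge_adjacent(once.rename(columns={}).assign(direction=once["direction"]))
        assert len(once) == len(again) == 2
        np.testing.assert_array_equal(once["start"].to_numpy(), again["start"].to_numpy())

    def test_chromosome_boundary_not_merged(self):
        rows = [("chr1", 500, 1000, 2.0, 0.001, "hyper"),
                ("chr2", 0, 500, 2.0, 0.001, "hyper")]
        assert len(merge_adjacent(flagged_frame(rows))) == 2


def dmr_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                       "fold", "p", "n_windows"])


class TestMaskDmrs:
    MASK = GenomicInterval("chr13", 58_060_780, 80_060_780)

    def test_inside_removed(self):
        dmrs = dmr_frame([("chr13", 60_000_000, 60_000_500, "hyper", 2, 0.001, 1)])
        assert len(mask_dmrs(dmrs, self.MASK)) == 0

    def test_book_ended_kept(self):
        dmrs = dmr_frame([("chr13", 80_060_780, 80_061_280, "hyper", 2, 0.001, 1)])
        assert len(mask_dmrs(dmrs, self.MASK)) == 1

    def test_one_bp_overlap_removed(self):
        dmrs = dmr_frame([("chr13", 80_060_779, 80_061_280, "hyper", 2, 0.001, 1)])
        assert len(mask_dmrs(dmrs, self.MASK)) == 0

    def test_other_chrom_kept(self):
        dmrs = dmr_frame([("chr1", 60_000_000, 60_000_500, "hyper", 2, 0.001, 1)])
        assert len(mask_dmrs(dmrs, self.MASK)) == 1

    def test_mask_merge_commute_when_disjoint(self):
        rows = [("chr1", 0, 500, 2.0, 0.001, "hyper"),
                ("chr1", 500, 1000, 2.0, 0.001, "hyper")]
        flg = flagged_frame(rows)
        mask = GenomicInterval("chr2", 0, 1000)
        a = mask_dmrs(merge_adjacent(flg), mask)
        b = merge_adjacent(mask_dmrs(flg.assign(n_windows=1), mask)
                           [["chrom", "start", "end", "fold", "p", "direction"]])
        np.testing.assert_array_equal(a["start"].to_numpy(), b["start"].to_numpy())


class TestCombineAndIntersect:
    def test_combined_count(self):
        lists = [dmr_frame([("chr1", i * 1000, i * 1000 + 500, "hyper", 2, 0.001, 1)
                            for i in range(n)]) for n in (91, 203, 599)]
        assert len(combine_lists(lists)) == 893

    def test_empty_inputs(self):
        assert len(combine_lists([dmr_frame([]), dmr_frame([])])) == 0

    def test_order_stable(self):
        a = dmr_frame([("chr1", 0, 500, "hyper", 2, 0.001, 1)])
        b = dmr_frame([("chr2", 0, 500, "hypo", 0.5, 0.001, 1)])
        out = combine_lists([a, b])
        assert list(out["chrom"]) == ["chr1", "chr2"]

    def test_identical_lists_all_common(self):
        a = dmr_frame([("chr1", 0, 500, "hyper", 2, 0.001, 1)])
        res = intersect_sets({"x": a, "y": a.copy(), "z": a.copy()})
        assert res["partition"] == {("x", "y", "z"): 3}

    def test_disjoint_all_unique(self):
        a = dmr_frame([("chr1", 0, 500, "hyper", 2, 0.001, 1)])
        b = dmr_frame([("chr1", 1000, 1500, "hyper", 2, 0.001, 1)])
        res = intersect_sets({"x": a, "y": b})
        assert res["partition"] == {("x",): 1, ("y",): 1}

    def test_one_bp_overlap_shared(self):
        a = dmr_frame([("chr1", 0, 500, "hyper", 2, 0.001, 1)])
        b = dmr_frame([("chr1", 400, 900, "hyper", 2, 0.001, 1)])
        res = intersect_sets({"x": a, "y": b})
        assert res["partition"] == {("x", "y"): 2}


class TestDmrBedIO:
    def test_roundtrip(self, tmp_path):
        dmrs = dmr_frame([("chr1", 0, 1500, "hyper", 2.5, 0.001, 3),
                          ("chr2", 100, 600, "hypo", 0.4, 0.005, 1)])
        path = tmp_path / "dmrs.bed"
        write_dmr_bed(dmrs, path)
        back = read_dmr_bed(path)
        assert len(back) == 2
        assert list(back["direction"]) == ["hyper", "hypo"]
        assert back["n_windows"].tolist() == [3, 1]
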