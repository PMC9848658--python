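"""Windowed diversity and divergence estimators against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsweep.popgen import (Window, dxy_site, dxy_window, make_windows,
                             site_pi, tajima_constants, tajimas_d,
                             watterson_theta, wc_fst_site, wc_fst_window,
                             window_pi, window_stats)
from popsweep.variants import MISSING, PopulationMap

from conftest import make_table


def brute_force_pi(n, c):
    """Fraction of haplotype pairs differing at a site, by enumeration."""
    haps = [1] * c + [0] * (n - c)
    pairs = list(itertools.combinations(haps, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


class TestSitePi:
    def test_monomorphic(self):
        assert site_pi(20, 0) == 0.0

    def test_exhaustive_pair_counting_all_n_up_to_8(self):
        for n in range(2, 9):
            for c in range(n + 1):
                assert site_pi(n, c) == pytest.approx(brute_force_pi(n, c))

    def test_worked_values(self):
        assert site_pi(4, 2) == pytest.approx(2 / 3)
        assert site_pi(30, 15) == pytest.approx(450 / 870)

    def test_undefined_below_two_alleles(self):
        assert math.isnan(site_pi(1, 0))


class TestWindowPi:
    def test_no_polymorphic_sites(self):
        assert window_pi([], Window("c", 1, 1000)) == 0.0

    def test_per_bp(self):
        assert window_pi([2 / 3], Window("c", 1, 1000)) == pytest.approx(6.667e-4,
                                                                         rel=1e-3)

    def test_per_snp(self):
        assert window_pi([0.5, 0.1], Window("c", 1, 1000),
                         denominator="snp") == pytest.approx(0.3)


class TestWattersonTheta:
    def test_zero_segregating(self):
        assert watterson_theta(0, 10, 1000) == 0.0

    def test_worked(self):
        assert watterson_theta(3, 4, 1) == pytest.approx(3 / (1 + 1 / 2 + 1 / 3))
        assert watterson_theta(3, 4, 1000) == pytest.approx(1.63636e-3, rel=1e-4)


class TestTajimasD:
    def test_constants_n4(self):
        k = tajima_constants(4)
        assert k["a1"] == pytest.approx(1.833333, abs=1e-6)
        assert k["e1"] == pytest.approx(0.005510, abs=1e-5)
        assert k["e2"] == pytest.approx(0.002690, abs=1e-5)

    def test_zero_numerator(self):
        k = tajima_constants(10)
        assert tajimas_d(5, 5 / k["a1"], 10) == pytest.approx(0.0, abs=1e-12)

    def test_worked_n4(self):
        # derived counts {1, 2, 1}: S=3, pi_sum = 0.5 + 2/3 + 0.5
        assert tajimas_d(3, 0.5 + 2 / 3 + 0.5, 4) == pytest.approx(0.1677,
                                                                   abs=1e-3)

    def test_undefined_when_no_segregating_sites(self):
        assert math.isnan(tajimas_d(0, 0.0, 10))

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            tajimas_d(1, 0.5, 3)

    def test_scale_free(self):
        """D depends only on S, pi_sum and n, never on window length."""
        d1 = tajimas_d(7, 3.2, 20)
        assert d1 == tajimas_d(7, 3.2, 20)


class TestWeirCockerham:
    def test_fixed_difference(self):
        a, b, c = wc_fst_site(10, 1.0, 0.0, 10, 0.0, 0.0)
        assert (a, b, c) == pytest.approx((0.5, 0.0, 0.0))
        assert wc_fst_window([(a, b, c)]) == pytest.approx(1.0)

    def test_both_fixed_same_allele_contributes_nothing(self):
        a, b, c = wc_fst_site(10, 0.0, 0.0, 10, 0.0, 0.0)
        assert a == b == c == 0.0
        assert math.isnan(wc_fst_window([(a, b, c)]))

    def test_worked_components(self):
        a, b, c = wc_fst_site(10, 0.8, 0.4, 10, 0.3, 0.6)
        assert a == pytest.approx(0.118333, abs=1e-6)
        assert b == pytest.approx(-0.058333, abs=1e-6)
        assert c == pytest.approx(0.25, abs=1e-12)
        assert wc_fst_window([(a, b, c)]) == pytest.approx(0.38172, abs=1e-5)

    def test_all_fixed_different_window(self):
        comps = [wc_fst_site(10, 1.0, 0.0, 10, 0.0, 0.0)] * 5
        assert wc_fst_window(comps) == pytest.approx(1.0)


class TestDxy:
    @pytest.mark.parametrize("p1,p2,expected", [(0, 0, 0), (1, 0, 1),
                                                (0.5, 0.25, 0.5)])
    def test_analytic_cases(self, p1, p2, expected):
        assert dxy_site(p1, p2) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_symmetric_and_bounded(self, p1, p2):
        assert dxy_site(p1, p2) == pytest.approx(dxy_site(p2, p1))
        assert 0.0 <= dxy_site(p1, p2) <= 1.0

    def test_window_forms(self):
        assert dxy_window([1.0], [0.0], Window("c", 1, 1000)) == pytest.approx(1e-3)
        assert dxy_window([1.0, 0.5], [0.0, 0.5],
                          Window("c", 1, 2)) == pytest.approx(0.75)
        assert dxy_window([], [], Window("c", 1, 100)) == 0.0


class TestMakeWindows:
    def test_exact_tiling(self):
        w = make_windows({"c": 100}, 50, 50)
        assert [(x.start, x.end) for x in w] == [(1, 50), (51, 100)]

    def test_truncated_tail(self):
        w = make_windows({"c": 120}, 50, 50)
        assert (w[-1].start, w[-1].end) == (101, 120)

    def test_overlapping_steps(self):
        w = make_windows({"c": 100}, 50, 25)
        assert [x.start for x in w] == [1, 26, 51, 76]


class TestWindowStats:
    def test_permutation_invariance(self):
        """Window statistics ignore sample order within a population."""
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        table = make_table(g, positions=list(rng.choice(10_000, 50, replace=False) + 1))
        table.sites.sort_values("pos", inplace=True, ignore_index=True)
        pm = PopulationMap(assignments={s: ("pop1" if i < 4 else "pop2")
                                       for i, s in enumerate(table.samples)})
        windows = make_windows({"chr1": 10_000}, 5_000)
        base = window_stats(table, pm, windows)
        perm = [3, 1, 0, 2, 7, 4, 6, 5]
        table2 = make_table(g[:, perm], positions=list(table.sites["pos"]),
                            samples=[table.samples[i] for i in perm])
        shuffled = window_stats(table2, pm, windows)
        for col in ("pi_pop1", "pi_pop2", "fst", "dxy", "tajima_d_pop1"):
            np.testing.assert_allclose(base[col], shuffled[col], equal_nan=True)

    def test_undefined_is_nan_not_zero(self, toy_popmap):
        table = make_table([[MISSING, MISSING, 1, 1]])
        windows = [Window("chr1", 1, 1000)]
        df = window_stats(table, toy_popmap, windows)
        assert math.isnan(df["fst"].iloc[0])
        assert math.isnan(df["tajima_d_pop1"].iloc[0])
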