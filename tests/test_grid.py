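"""Occupancy grids, box-count curves, and fractal-dimension fits."""

import math

import numpy as np
import pytest
from scipy import stats

from tilspatial.grid import (BinaryQuestion, BoxCountCurve, GridSpec,
                             InsufficientScalesError, fd_difference,
                             fit_fractal_dimension, occupancy_auc,
                             occupancy_curve, overlay_counts)
from tilspatial.synthetic import (Window, expected_poisson_occupancy,
                                  sample_poisson, sample_thomas)
from conftest import make_pattern

import pandas as pd

B_Q = BinaryQuestion.b_cells()
T_Q = BinaryQuestion.t_cells()


class TestOverlayCounts:
    def test_single_cell_fully_occupies_for_every_L(self):
        pat = make_pattern([(5.0, 5.0, "B", "stroma")])
        for L in (10, 50, 600):
            n, N, occ = overlay_counts(pat, L, B_Q)
            assert (n, N, occ) == (1, 1, 1.0)

    def test_hand_placed_quadrants(self):
        # four cells in the four L=10 squares of a 20x20 block
        pat = make_pattern([(5, 5, "B", "stroma"), (15, 5, "B", "stroma"),
                            (5, 15, "B", "stroma"), (15, 15, "B", "stroma")])
        n, N, occ = overlay_counts(pat, GridSpec(10.0, (0.0, 0.0)), B_Q)
        assert (n, N, occ) == (4, 4, 1.0)
        n, N, occ = overlay_counts(pat, GridSpec(20.0, (0.0, 0.0)), B_Q)
        assert (n, N, occ) == (1, 1, 1.0)

    def test_question_matching_nothing_gives_zero_occupancy(self):
        pat = make_pattern([(5, 5, "T", "stroma"), (250, 250, "T", "stroma")])
        n, N, occ = overlay_counts(pat, 100.0, B_Q)
        assert n == 0 and N > 0 and occ == 0.0

    def test_tissue_scope_filters_question_but_not_N(self):
        pat = make_pattern([(5, 5, "B", "cancer_island"),
                            (255, 255, "B", "stroma")])
        n, N, _ = overlay_counts(pat, 100.0, BinaryQuestion.b_cells("stroma"))
        assert N == 2 and n == 1

    def test_empty_pattern_rejected(self):
        pat = make_pattern([(0, 0, "B", "stroma")])
        pat.cells = pat.cells.iloc[:0]
        with pytest.raises(ValueError):
            overlay_counts(pat, 10.0, B_Q)

    def test_membership_scope_requires_cluster_map(self):
        pat = make_pattern([(0, 0, "B", "stroma")])
        q = BinaryQuestion(frozenset({"B"}), membership_scope="in_lc_only")
        with pytest.raises(ValueError, match="membership"):
            overlay_counts(pat, 10.0, q)


class TestOccupancyCurve:
    def test_single_cell_curve_is_constant_one(self):
        pat = make_pattern([(3.0, 4.0, "B", "stroma")])
        curve = occupancy_curve(pat, [10, 20, 40], B_Q)
        assert np.allclose(curve.occupancy, 1.0)

    def test_counts_bounded_and_occupancy_in_unit_interval(self):
        pat = sample_poisson(200.0, Window(1000, 1000), seed=5)
        curve = occupancy_curve(pat, [10, 25, 60, 150, 400], B_Q)
        assert (curve.n <= curve.N).all()
        assert ((curve.occupancy >= 0) & (curve.occupancy <= 1)).all()

    def test_dyadic_nesting_makes_n_nonincreasing(self):
        # with a shared origin, each L-square lies inside one 2L-square
        pat = sample_poisson(300.0, Window(2000, 2000), seed=7)
        curve = occupancy_curve(pat, [10, 20, 40, 80], B_Q)
        assert (np.diff(curve.n) <= 0).all()

    def test_poisson_occupancy_matches_closed_form(self):
        # binomial 99% CI around 1 - exp(-lambda L^2), boxes independent
        lam = 300.0
        pat = sample_poisson(lam, Window(3000, 3000), seed=21)
        curve = occupancy_curve(pat, [10, 20, 40, 100], B_Q,
                                count_all_squares=True)
        for L, occ, N in zip(curve.L, curve.occupancy, curve.N):
            p = expected_poisson_occupancy(lam, L)
            half_width = 2.576 * math.sqrt(p * (1 - p) / N)
            assert abs(occ - p) < max(half_width, 3.0 / N)

    def test_strictly_increasing_L_enforced(self):
        frame = pd.DataFrame({"L": [10.0, 10.0], "n": [1, 1],
                              "N": [1, 1], "occupancy": [1.0, 1.0]})
        with pytest.raises(ValueError):
            BoxCountCurve(frame)


class TestOccupancyAUC:
    def test_constant_one_integrates_to_log_range(self):
        frame = pd.DataFrame({"L": [10.0, 600.0], "n": [5, 5],
                              "N": [5, 5], "occupancy": [1.0, 1.0]})
        auc = occupancy_auc(BoxCountCurve(frame))
        assert math.isclose(auc, math.log(60.0), rel_tol=1e-12)

    def test_zero_occupancy_gives_zero(self):
        frame = pd.DataFrame({"L": [10.0, 100.0], "n": [0, 0],
                              "N": [5, 5], "occupancy": [0.0, 0.0]})
        assert occupancy_auc(BoxCountCurve(frame)) == 0.0

    def test_two_point_trapezoid_by_hand(self):
        frame = pd.DataFrame({"L": [10.0, 100.0], "n": [1, 4],
                              "N": [5, 5], "occupancy": [0.2, 0.8]})
        auc = occupancy_auc(BoxCountCurve(frame))
        assert math.isclose(auc, 0.5 * (0.2 + 0.8) * math.log(10.0),
                            rel_tol=1e-12)

    def test_linear_abscissa_option(self):
        frame = pd.DataFrame({"L": [10.0, 110.0], "n": [1, 1],
                              "N": [2, 2], "occupancy": [0.5, 0.5]})
        assert math.isclose(
            occupancy_auc(BoxCountCurve(frame), abscissa="linear"), 50.0)

    def test_single_entry_rejected(self):
        frame = pd.DataFrame({"L": [10.0], "n": [1], "N": [1],
                              "occupancy": [1.0]})
        with pytest.raises(ValueError):
            occupancy_auc(BoxCountCurve(frame))


class TestFractalDimension:
    def test_single_cell_slope_zero(self):
        pat = make_pattern([(100.0, 100.0, "B", "stroma"),
                            (900.0, 900.0, "T", "stroma")])
        fit = fit_fractal_dimension(pat, B_Q, Ls=[10, 20, 40, 80],
                                    scale_window=(10, 80))
        assert fit.slope_s == pytest.approx(0.0, abs=1e-12)

    def test_dense_lattice_is_area_filling(self):
        # 1 um grid spacing: every box occupied, n = area / L^2, slope = 2
        step = 1.0
        xs = np.arange(0, 1200.0, step)
        xy = np.stack(np.meshgrid(xs[::4], xs[::4]), axis=-1).reshape(-1, 2)
        rows = [(x, y, "B", "stroma") for x, y in xy]
        pat = make_pattern(rows, area_mm2=1.44)
        fit = fit_fractal_dimension(pat, B_Q, Ls=[200, 300, 400, 600],
                                    scale_window=(200, 600))
        assert fit.slope_s == pytest.approx(2.0, abs=0.02)
        assert fit.r_squared > 0.999

    def test_poisson_small_scale_slope_matches_closed_form(self):
        # least-squares slope on n(L) ∝ (1 - exp(-lam L^2)) / L^2
        lam_mm2 = 300.0
        Ls = np.array([10.0, 15, 20, 30, 40])
        lnN = np.log((1 - np.exp(-lam_mm2 / 1e6 * Ls ** 2)) / Ls ** 2)
        expected = stats.linregress(np.log(1 / Ls), lnN).slope
        assert expected == pytest.approx(0.152, abs=0.002)
        slopes = [fit_fractal_dimension(
            sample_poisson(lam_mm2, Window(3000, 3000), seed=s), B_Q,
            Ls=Ls, scale_window=(10, 40)).slope_s for s in range(10)]
        assert np.mean(slopes) == pytest.approx(expected, abs=0.02)

    def test_slope_invariant_to_multiplying_counts(self):
        # translation of ln n leaves the least-squares slope unchanged
        Ls = np.array([10.0, 20, 40, 80])
        n = np.array([50.0, 30, 14, 5])
        s1 = stats.linregress(np.log(1 / Ls), np.log(n)).slope
        s2 = stats.linregress(np.log(1 / Ls), np.log(7.0 * n)).slope
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_two_point_slopes_bounded_by_dimension(self):
        # nesting: n(2L) <= n(L) <= 4 n(2L) so dyadic slopes lie in [0, 2]
        pat = sample_poisson(400.0, Window(1500, 1500), seed=3)
        curve = occupancy_curve(pat, [10, 20, 40, 80, 160], B_Q)
        n, L = curve.n.astype(float), curve.L
        for i in range(len(L) - 1):
            slope = (np.log(n[i + 1]) - np.log(n[i])) / (
                np.log(1 / L[i + 1]) - np.log(1 / L[i]))
            assert -1e-9 <= slope <= 2 + 1e-9

    def test_insufficient_scales_raise(self):
        pat = make_pattern([(5, 5, "B", "stroma")])
        with pytest.raises(InsufficientScalesError):
            fit_fractal_dimension(pat, T_Q, Ls=[10, 20, 40],
                                  scale_window=(10, 40))


class TestFDDifference:
    def test_single_cell_delta_zero(self):
        pat = make_pattern([(100.0, 100.0, "B", "stroma"),
                            (2900.0, 2900.0, "T", "stroma")])
        dd = fd_difference(pat, B_Q)
        assert dd.delta_s == pytest.approx(0.0, abs=1e-12)
        assert dd.delta_s == dd.s_large - dd.s_small

    def test_poisson_delta_matches_analytic_slopes(self):
        deltas = [fd_difference(
            sample_poisson(300.0, Window(3000, 3000), seed=s), B_Q).delta_s
            for s in range(20)]
        assert np.mean(deltas) == pytest.approx(1.85, abs=0.15)

    def test_clustering_lowers_delta_vs_matched_poisson(self):
        # same expected intensity; clustered points cover fewer big boxes
        wins = 0
        for s in range(20):
            thomas = sample_thomas(10.0, 30.0, 15.0, Window(3000, 3000),
                                   seed=s)
            poisson = sample_poisson(300.0, Window(3000, 3000), seed=1000 + s)
            wins += (fd_difference(thomas, B_Q).delta_s
                     < fd_difference(poisson, B_Q).delta_s)
        assert wins >= 18
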