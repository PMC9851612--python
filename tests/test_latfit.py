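"""Latency extraction: Gaussian fits, piecewise windows, latency lines."""

import numpy as np
import pytest
from scipy import stats

from mvextrap.latfit import (
    LatencyLine,
    adjusted_r2,
    bootstrap_peak_ci,
    compare_lines,
    feedforward_window,
    fit_gaussian,
    fit_latency_line,
    gaussian_curve,
    mean_line_distance,
    motion_peak_times,
    piecewise_fit,
    select_knot_count,
    static_peak_times,
)

T128 = np.arange(-64, 65) * 1000.0 / 128.0  # [-500, 500] ms at 128 Hz


class TestGaussianFit:
    def test_noiseless_in_model_data_recovered_exactly(self):
        truth = (0.01, 50.0, 30.0, 0.027)
        y = gaussian_curve(T128, *truth)
        fit = fit_gaussian(y, T128)
        assert fit.converged
        assert np.allclose(fit.params, truth, atol=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_data_fails_the_quality_gate(self):
        fit = fit_gaussian(np.full(T128.size, 0.027), T128)
        assert fit.adj_r2 <= 0.0

    def test_peak_recovery_under_ten_percent_noise(self):
        # b2 recovered within one 128 Hz sample for the vast majority of draws
        truth = (0.02, 120.0, 60.0, 0.027)
        clean = gaussian_curve(T128, *truth)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 0.1 * truth[0], size=T128.size)
            fit = fit_gaussian(y, T128)
            errs.append(abs(fit.b2 - truth[1]))
        assert np.median(errs) <= 1000.0 / 128.0
        assert np.mean(np.array(errs) <= 1000.0 / 128.0) >= 0.9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian(np.zeros(5), np.arange(5.0))


class TestAdjustedR2:
    def test_hand_value(self):
        assert adjusted_r2(0.9, n=10, n_params=4) == pytest.approx(0.82)

    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, n=20) == 1.0

    def test_mean_prediction_nonpositive(self):
        assert adjusted_r2(0.0, n=12) <= 0.0

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, n=5)


class TestPeakSeries:
    def test_static_argmax_with_earliest_tie(self):
        test_t = np.arange(0, 45) * 1000.0 / 128.0
        tgm = np.zeros((3, test_t.size))
        tgm[0, 10] = 1.0
        tgm[1, :] = 0.5  # all equal -> earliest
        tgm[2, [20, 30]] = [0.9, 0.9]  # tie -> earliest of the two
        ps = static_peak_times(tgm, np.arange(3.0), test_t)
        assert ps.peak_times_ms[0] == pytest.approx(test_t[10])
        assert ps.peak_times_ms[1] == pytest.approx(test_t[0])
        assert ps.peak_times_ms[2] == pytest.approx(test_t[20])

    def test_motion_peaks_gate_excludes_flat_rows(self):
        tgm = np.vstack([gaussian_curve(T128, 0.02, 60.0, 80.0, 0.027),
                         np.full(T128.size, 0.027)])
        ps, fits = motion_peak_times(tgm, np.array([0.0, 1.0]), T128)
        assert ps.included.tolist() == [True, False]
        assert ps.peak_times_ms[0] == pytest.approx(60.0, abs=1e-3)


class TestPiecewise:
    def test_single_line_is_exact_for_any_knot_count(self):
        x = np.linspace(0, 300, 40)
        y = 0.8 * x + 12.0
        for n in (2, 4, 5, 6, 7):
            pw = piecewise_fit(x, y, n)
            assert pw.r2 == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(pw.segment_slopes(), 0.8, atol=1e-6)

    def test_v_shape_breakpoint_recovered(self):
        x = np.linspace(0, 300, 61)
        y = np.where(x < 150, 150 - x, x - 150).astype(float)
        pw = piecewise_fit(x, y, 3)
        assert abs(pw.knots_ms[1] - 150.0) <= 5.0 + 1e-9  # x-grid resolution
        assert pw.r2 > 0.999

    def test_rmse_nonincreasing_in_knot_count(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 350, 45)
        y = np.sin(x / 60.0) * 30 + rng.normal(0, 3, size=x.size)
        rmses = [piecewise_fit(x, y, n).rmse for n in (2, 3, 4, 5, 6, 7)]
        assert all(b <= a + 0.3 for a, b in zip(rmses, rmses[1:]))

    def test_knot_selection_prefers_fewest_on_ties(self):
        x = np.linspace(0, 300, 40)
        y = 2.0 * x + 5.0  # every candidate fits exactly -> pick 4
        best = select_knot_count(x, y, candidates=(4, 5, 6, 7))
        assert best.n_knots == 4

    def test_feedforward_window_is_start_to_first_interior_knot(self):
        x = np.linspace(40, 240, 30)
        y = np.where(x < 158, x, 158.0 + 0.05 * (x - 158))
        pw = select_knot_count(x, y, candidates=(3, 4))
        lo, hi = feedforward_window(pw)
        assert lo == pytest.approx(40.0, abs=1e-6)
        assert abs(hi - 158.0) <= 12.0
        # single-segment fit spans the full range
        single = piecewise_fit(x, y, 2)
        assert feedforward_window(single) == (pytest.approx(40.0), pytest.approx(240.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            piecewise_fit(np.arange(4.0), np.arange(4.0), 7)


def textbook_ols(x, y):
    """Independent oracle: normal equations + classic F/t formulas."""
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    se_slope = np.sqrt(s2 / sxx)
    t_slope = slope / se_slope
    ss_reg = np.sum((intercept + slope * x - y.mean()) ** 2)
    F = ss_reg / s2
    p_F = stats.f.sf(F, 1, n - 2)
    return slope, intercept, t_slope, F, p_F


class TestLatencyLine:
    def test_exact_line(self):
        x = np.linspace(0, 10, 12)
        line = fit_latency_line(x, 2.0 * x + 1.0)
        assert line.slope == pytest.approx(2.0, abs=1e-10)
        assert line.intercept_ms == pytest.approx(1.0, abs=1e-10)
        assert line.r2 == pytest.approx(1.0)

    def test_hand_ols_three_points(self):
        line = fit_latency_line(np.array([0.0, 1.0, 2.0]), np.array([1.0, 3.0, 4.0]))
        assert line.slope == pytest.approx(1.5, abs=1e-12)
        assert line.intercept_ms == pytest.approx(7.0 / 6.0, abs=1e-12)

    def test_inference_matches_textbook_oracle(self):
        rng = np.random.default_rng(11)
        x = np.linspace(75, 158, 12)
        y = 0.9 * x - 40 + rng.normal(0, 8, size=x.size)
        line = fit_latency_line(x, y)
        slope, intercept, t_slope, F, p_F = textbook_ols(x, y)
        assert line.slope == pytest.approx(slope, abs=1e-10)
        assert line.intercept_ms == pytest.approx(intercept, abs=1e-10)
        assert line.slope_t == pytest.approx(t_slope, abs=1e-10)
        assert line.f_vs_constant == pytest.approx(F, abs=1e-8)
        assert line.p_f == pytest.approx(p_F, abs=1e-10)
        lo, hi = line.slope_ci
        assert lo < slope < hi

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_latency_line(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestCompareLines:
    def test_identical_lines_give_zero_differences(self):
        x = np.linspace(75, 158, 10)
        y = 0.9 * x + 5
        a = fit_latency_line(x, y, "static")
        b = fit_latency_line(x, y, "motion")
        cmp = compare_lines(a, b, (75.0, 158.0))
        assert cmp.slope_diff == pytest.approx(0.0, abs=1e-10)
        assert cmp.intercept_diff_ms == pytest.approx(0.0, abs=1e-10)
        assert cmp.mean_distance_ms == pytest.approx(0.0, abs=1e-10)

    def test_printed_line_arithmetic(self):
        static = LatencyLine.from_params(0.85, 19.0, "static")
        motion = LatencyLine.from_params(1.09, -82.0, "motion")
        cmp = compare_lines(static, motion, (75.0, 158.0))
        assert round(cmp.mean_distance_ms) == 73
        assert round(float(static.predict(75.0))) == 83

    def test_mean_distance_independent_of_sampling(self):
        a = LatencyLine.from_params(0.85, 19.0)
        b = LatencyLine.from_params(1.09, -82.0)
        analytic = mean_line_distance(a, b, (75.0, 158.0))
        for n in (7, 70, 700):
            t = np.linspace(75.0, 158.0, n)
            assert np.mean(a.predict(t) - b.predict(t)) == pytest.approx(analytic, abs=1e-9)

    def test_interaction_regression_detects_intercept_shift(self):
        rng = np.random.default_rng(12)
        x = np.linspace(75, 158, 12)
        a = fit_latency_line(x, x + rng.normal(0, 2, x.size), "static")
        b = fit_latency_line(x, x - 80 + rng.normal(0, 2, x.size), "motion")
        cmp = compare_lines(a, b, (75.0, 158.0))
        assert cmp.intercept_diff_p < 0.01
        assert cmp.slope_diff_p > 0.05

    def test_disjoint_window_rejected(self):
        a = LatencyLine.from_params(1.0, 0.0)
        with pytest.raises(ValueError):
            compare_lines(a, a, (100.0, 50.0))


class TestBootstrap:
    def test_zero_between_participant_variance_gives_zero_width(self):
        y = gaussian_curve(T128, 0.02, 40.0, 60.0, 0.027)
        stack = np.tile(y, (8, 1))
        lo, hi = bootstrap_peak_ci(stack, T128, n_boot=50, seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(13)
        stack = gaussian_curve(T128, 0.02, 90.0, 70.0, 0.027) \
            + rng.normal(0, 0.002, size=(10, T128.size))
        ci1 = bootstrap_peak_ci(stack, T128, n_boot=60, seed=4)
        ci2 = bootstrap_peak_ci(stack, T128, n_boot=60, seed=4)
        assert ci1 == ci2

    def test_coverage_near_nominal(self):
        # 95% percentile CI should cover the true peak in >= 90/100 draws
        truth = 90.0
        clean = gaussian_curve(T128, 0.02, truth, 70.0, 0.027)
        covered = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            stack = clean + rng.normal(0, 0.004, size=(16, T128.size))
            lo, hi = bootstrap_peak_ci(stack, T128, n_boot=199, seed=rep)
            covered += lo <= truth <= hi
        assert covered >= 90

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_peak_ci(np.zeros((1, 50)), np.arange(50.0), n_boot=10)
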