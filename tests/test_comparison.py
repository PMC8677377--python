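import numpy as np
import pytest

from movecompare.comparison import (
    CycleWindow,
    Thresholds,
    WindowTooShortError,
    compare_series,
    fit_path_line,
    localize_discrepancy,
    mean_line_difference,
    r_squared,
    select_cycle_window,
)
from movecompare.io_signals import MagnitudeSeries
from movecompare.synthetic import SignalSpec, generate_pair, generate_signal
from movecompare.warping import WarpPath, cost_matrix, greedy_path


def make_path(points):
    pts = np.array(points, dtype=int)
    return WarpPath(points=pts, method="greedy", total_cost=0.0)


class TestSelectCycleWindow:
    @pytest.mark.parametrize(
        "period, k, expected",
        [(124, 3, (372, 496)), (124, 6, (744, 868)), (125, 13, (1625, 1750))],
    )
    def test_window_arithmetic(self, period, k, expected):
        w = select_cycle_window(2900, period, seed=None, k=k)
        assert (w.initial_sample, w.final_sample) == expected
        assert w.n_samples == period + 1

    def test_random_draw_within_limits(self):
        for seed in range(30):
            w = select_cycle_window(1000, 124, seed=seed)
            limit = 1000 // 124 - 1
            assert 1 <= w.k <= limit
            assert w.final_sample - w.initial_sample == 124
            assert w.final_sample <= 1000

    def test_deterministic_given_seed(self):
        a = select_cycle_window(3000, 124, seed=42)
        b = select_cycle_window(3000, 124, seed=42)
        assert a == b

    def test_too_short_rejected(self):
        with pytest.raises(WindowTooShortError):
            select_cycle_window(200, 124, seed=0)


class TestFitPathLine:
    def test_identity_path(self):
        m, b = fit_path_line(make_path([(i, i) for i in range(1, 10)]))
        assert m == pytest.approx(1.0)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_exact_collinear(self):
        m, b = fit_path_line(make_path([(1, 2), (2, 4), (3, 6)]))
        assert m == pytest.approx(2.0)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_i_rejected(self):
        with pytest.raises(ValueError):
            fit_path_line(make_path([(1, 1), (1, 2), (1, 3)]))


class TestRSquared:
    def test_identity_path_is_one(self):
        path = make_path([(i, i) for i in range(1, 8)])
        assert r_squared(path, fit_path_line(path)) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # OLS of {(1,1),(2,3),(3,2),(4,4)}: m=0.8, b=0.5, SSres=1.8, SStot=5
        path = make_path([(1, 1), (2, 3), (3, 2), (4, 4)])
        fit = fit_path_line(path)
        assert fit == (pytest.approx(0.8), pytest.approx(0.5))
        assert r_squared(path, fit) == pytest.approx(0.64)

    def test_constant_j_perfect_fit(self):
        path = make_path([(1, 2), (2, 2), (3, 2)])
        assert r_squared(path, (0.0, 2.0)) == 1.0


class TestMeanLineDifference:
    def test_ideal_line_zero(self):
        path = make_path([(i, i) for i in range(1, 6)])
        assert mean_line_difference((1.0, 0.0), path) == 0.0

    def test_constant_offset(self):
        path = make_path([(1, 3), (2, 9), (3, 1)])
        assert mean_line_difference((1.0, 5.0), path) == pytest.approx(5.0)

    def test_direct_summation_oracle(self):
        # mean of |0.9898 i + 24.4590 - i| over i = 372..496
        path = make_path([(i, i) for i in range(372, 497)])
        expected = np.mean(np.abs(0.9898 * np.arange(372, 497) + 24.4590 - np.arange(372, 497)))
        assert mean_line_difference((0.9898, 24.4590), path) == pytest.approx(expected)
        assert expected == pytest.approx(20.0322)

    def test_depends_only_on_fit_and_i_coordinates(self):
        fit = (0.97, 3.0)
        a = make_path([(i, i) for i in range(1, 50)])
        b = make_path([(i, (i * 7) % 50 + 1) for i in range(1, 50)])
        assert mean_line_difference(fit, a) == mean_line_difference(fit, b)


class TestVerdict:
    @pytest.mark.parametrize(
        "periods_ok, r2, diff, expected",
        [
            (True, 0.9867, 0.903803, "similar"),
            (True, 0.8482, 6.355008, "different"),
            (True, 0.9099, 15.80045, "different"),
            (False, None, None, "different"),
        ],
    )
    def test_three_criteria(self, periods_ok, r2, diff, expected):
        from movecompare.comparison import _verdict

        verdict, reasons = _verdict(periods_ok, r2, diff, Thresholds())
        assert verdict == expected
        if expected == "different":
            assert reasons

    def test_thresholds_configurable(self):
        from movecompare.comparison import _verdict

        verdict, _ = _verdict(True, 0.95, 12.0, Thresholds(diff_max=20.0))
        assert verdict == "similar"


class TestLocalizeDiscrepancy:
    def test_identical_windows_no_segments(self):
        w = np.sin(np.linspace(0, 6, 100)) * 5000 + 5000
        path = greedy_path(cost_matrix(w, w))
        assert localize_discrepancy(w, w, path) == []

    def test_injected_distortion_is_localized(self):
        rng = np.random.default_rng(0)
        v = 5000 + 4000 * np.sin(2 * np.pi * np.arange(125) / 125)
        u = v.copy()
        u[50:75] = v[50:75][::-1] * 0.3  # corrupt only samples 51..75
        path = greedy_path(cost_matrix(v, u))
        segments = localize_discrepancy(v, u, path)
        assert segments
        lo = min(s for s, _ in segments)
        hi = max(e for _, e in segments)
        assert lo <= 75 and hi >= 51  # overlaps the corrupted range

    def test_fully_different_windows_span_window(self):
        v = np.linspace(0, 10000, 60)
        u = np.linspace(10000, 0, 60)
        path = greedy_path(cost_matrix(v, u))
        segments = localize_discrepancy(v, u, path)
        assert segments
        total = sum(e - s + 1 for s, e in segments)
        assert total >= 30  # most of the window flagged


class TestCompareSeriesEndToEnd:
    def test_self_comparison_identity(self, gait_series):
        rep = compare_series(gait_series, gait_series, seed=9)
        assert rep.verdict == "similar"
        assert rep.m == pytest.approx(1.0)
        assert rep.b == pytest.approx(0.0, abs=1e-12)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.mean_line_diff == 0.0
        assert rep.discrepant_segments == []
        assert rep.shift_applied == 0

    def test_tempo_mismatch_fails_period_gate(self):
        spec = SignalSpec(waveform="gait", noise_sd=0.0, seed=3)
        expert, learner, label = generate_pair(spec, "tempo", 0.5)
        assert label == "different"
        rep = compare_series(expert, learner, seed=1)
        assert rep.verdict == "different"
        assert not rep.periods_equal
        assert "periods differ" in rep.reasons

    def test_amplitude_scaling_is_tolerated(self):
        spec = SignalSpec(waveform="gait", noise_sd=0.0, seed=4)
        expert, learner, label = generate_pair(spec, "amplitude-scale", 1.8)
        assert label == "similar"
        rep = compare_series(expert, learner, seed=2)
        assert rep.verdict == "similar"

    def test_window_final_minus_initial_equals_period(self, gait_series):
        for seed in range(5):
            rep = compare_series(gait_series, gait_series, seed=seed)
            w = rep.window
            assert w.final_sample - w.initial_sample == rep.period_expert

    def test_dp_method_reported(self, gait_series):
        rep = compare_series(gait_series, gait_series, seed=0, path_method="dp")
        assert rep.path_method == "dp"
        assert rep.verdict == "similar"
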