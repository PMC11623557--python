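"""Segmented least squares: evaluation, fitting, metrics, THD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmcell.pwl_fit import (PiecewiseLinear, compute_metrics, compute_thd,
                            evaluate_pwl, fit_pwl, fit_pwl_fixed_breakpoints,
                            fit_pwl_sequence)

from .oracles import grid_pwl_sse, triangle_thd


class TestEvaluate:
    def test_single_segment_through_origin(self):
        pwl = PiecewiseLinear(T=np.array([10.0]), A=np.array([2.0]))
        assert evaluate_pwl(pwl, 3.0)[0] == pytest.approx(6.0)

    def test_continuity_recurrence_forced(self):
        pwl = PiecewiseLinear(T=np.array([5.0, 10.0]), A=np.array([1.0, -1.0]))
        assert evaluate_pwl(pwl, 5.0)[0] == pytest.approx(5.0)
        assert evaluate_pwl(pwl, 7.0)[0] == pytest.approx(3.0)

    def test_domain_enforced(self):
        pwl = PiecewiseLinear(T=np.array([1.0]), A=np.array([1.0]))
        with pytest.raises(ValueError, match="domain"):
            evaluate_pwl(pwl, 2.0)
        with pytest.raises(ValueError, match="domain"):
            evaluate_pwl(pwl, -0.1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_per_segment_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 7)
        T = np.sort(rng.uniform(0.1, 10.0, n))
        T[-1] = 10.0
        if len(np.unique(T)) < n or np.any(np.diff(T) <= 0):
            T = np.linspace(10.0 / n, 10.0, n)
        A = rng.normal(size=n)
        B1 = rng.normal()
        pwl = PiecewiseLinear(T, A, B1)
        ts = rng.uniform(0, 10.0, 1000)
        got = evaluate_pwl(pwl, ts)
        # brute-force segment lookup
        B = pwl.intercepts
        want = np.empty_like(ts)
        for i, x in enumerate(ts):
            k = 0
            while x > T[k]:
                k += 1
            want[i] = A[k] * x + B[k]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_continuity_at_breakpoints(self):
        rng = np.random.default_rng(1)
        pwl = PiecewiseLinear(np.array([1.0, 2.5, 4.0]), rng.normal(size=3),
                              B1=0.7)
        B = pwl.intercepts
        for k in range(pwl.n - 1):
            left = pwl.A[k] * pwl.T[k] + B[k]
            right = pwl.A[k + 1] * pwl.T[k] + B[k + 1]
            assert abs(left - right) < 1e-10


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.arange(5.0)
        m = compute_metrics(y, y)
        assert m.sse == 0.0 and m.rmse == 0.0 and m.r2 == 1.0

    def test_hand_arithmetic(self):
        m = compute_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert m.sse == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert m.r2 == pytest.approx(0.5)

    def test_zero_variance_flagged(self):
        m = compute_metrics([1.0, 1.0], [1.0, 2.0])
        assert m.r2 is None


class TestTHD:
    def test_pure_sine(self):
        n = 4096
        t = np.arange(n) / n  # one period of omega = 2 pi
        y = np.sin(2 * np.pi * t)
        assert compute_thd(y, t[1], 2 * np.pi) < 1e-10

    def test_triangle_matches_closed_form(self):
        n = 1 << 14
        t = np.arange(n) / n
        y = 2 * np.abs(2 * (t + 0.25) % 2 - 1) - 1  # symmetric triangle
        thd = compute_thd(y, t[1], 2 * np.pi)
        assert thd == pytest.approx(triangle_thd(), rel=1e-3)

    def test_non_integer_period_rejected(self):
        n = 1000
        t = np.arange(n) / n
        with pytest.raises(ValueError, match="integer"):
            compute_thd(np.sin(2 * np.pi * 1.5 * t), t[1], 2 * np.pi * 1.5)


class TestFit:
    def test_exactly_representable_signal_recovered(self):
        t = np.linspace(0, 10, 201)
        truth = PiecewiseLinear(np.array([5.0, 10.0]), np.array([1.0, -1.0]))
        y = evaluate_pwl(truth, t)
        pwl, m = fit_pwl(t, y, 2, seed=0, restarts=4)
        assert m.sse < 1e-16 * len(t)
        np.testing.assert_allclose(pwl.A, truth.A, atol=1e-6)
        assert pwl.T[0] == pytest.approx(5.0, abs=1e-4)

    def test_infeasible_segment_count(self):
        with pytest.raises(ValueError, match="too few"):
            fit_pwl(np.linspace(0, 1, 8), np.zeros(8), 4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 120)
        y = np.sin(6 * t) + 0.01 * rng.normal(size=120)
        a = fit_pwl(t, y, 3, seed=9, restarts=4)
        b = fit_pwl(t, y, 3, seed=9, restarts=4)
        np.testing.assert_array_equal(a[0].T, b[0].T)
        np.testing.assert_array_equal(a[0].A, b[0].A)

    def test_monotone_improvement_with_segments(self):
        t = np.linspace(0, 1, 300)
        y = np.sin(7.0 * t) * np.exp(-t)
        fits = fit_pwl_sequence(t, y, [1, 2, 3, 4, 5], seed=0, restarts=4)
        sses = [m.sse for _, m in fits]
        assert all(b <= a + 1e-12 for a, b in zip(sses, sses[1:]))

    def test_beats_grid_oracle_on_small_signals(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n_samp = rng.integers(30, 80)
            t = np.linspace(0, 1, n_samp)
            y = np.sin(rng.uniform(3, 9) * t) + 0.05 * rng.normal(size=n_samp)
            n_seg = int(rng.integers(2, 4))
            pwl, m = fit_pwl(t, y, n_seg, seed=0, restarts=4)
            assert m.sse <= grid_pwl_sse(t, y, n_seg) + 1e-10

    def test_free_intercept_handles_offset_signals(self):
        t = np.linspace(0, 1, 100)
        y = 5.0 - 2.0 * t
        pwl, m = fit_pwl(t, y, 1, free_intercept=True)
        assert m.sse < 1e-18 * len(t) + 1e-15
        assert pwl.B1 == pytest.approx(5.0)

    def test_fixed_breakpoint_fit_continuity(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 2, 400)
        y = np.cos(5 * t) + 0.1 * rng.normal(size=400)
        pwl, _ = fit_pwl_fixed_breakpoints(t, y, np.array([0.5, 1.1, 2.0]),
                                           free_intercept=True)
        B = pwl.intercepts
        for k in range(pwl.n - 1):
            left = pwl.A[k] * pwl.T[k] + B[k]
            right = pwl.A[k + 1] * pwl.T[k] + B[k + 1]
            assert abs(left - right) < 1e-10

    def test_ramp_and_sine_regression_regime(self):
        """Trapezoidal-ramp and sine targets are reproduced with R^2 > 0.99."""
        t = np.linspace(0, 1, 2000)
        rise, plateau = 0.25, 0.25
        trap = np.minimum(np.clip(t / rise, 0, 1),
                          np.clip((1 - t) / (1 - rise - plateau), 0, 1))
        _, m1 = fit_pwl(t, trap, 6, seed=0, restarts=4, free_intercept=True)
        assert m1.r2 > 0.99
        sine = 42.5 * np.sin(2.0 * np.pi * t)
        _, m2 = fit_pwl(t, sine, 12, seed=0, restarts=4)
        assert m2.r2 > 0.99
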