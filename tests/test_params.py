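"""Peak-selection rules, GLS, and strain-rate differentiation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strainpost import (
    EventTiming,
    PeakRule,
    SegmentModel,
    StrainTrace,
    aha18_labels,
    compute_gls,
    peak_echopac,
    peak_window_min,
    strain_rate_from_strain,
)
from strainpost.errors import UsageError

EVENTS = EventTiming(qrs1=0, mvc=30, avo=80, avc=380, mvo=460, p_onset=700, qrs2=850)
T = np.arange(0.0, 851.0, 10.0)  # AVC at 380 ms lies on the grid


def brute_force_min(t, curve, events):
    """Independent oracle: scan the window sample by sample."""
    best_v, best_t = None, None
    for ti, vi in zip(t, curve):
        if events.qrs1 <= ti <= events.avc and (best_v is None or vi < best_v):
            best_v, best_t = vi, ti
    return best_v, best_t


def brute_force_echopac(t, curve, events):
    """Independent oracle: enumerate the rule's branches explicitly."""
    window = [(ti, vi) for ti, vi in zip(t, curve) if events.qrs1 <= ti <= events.avc]
    n_val = min(v for _, v in window)
    p_val = max(v for _, v in window)
    if n_val >= 0:
        chosen = p_val
    elif p_val > 0.75 * abs(n_val):
        chosen = p_val
    else:
        chosen = n_val
    return chosen


def random_curve(rng, scale=20.0):
    """Smooth-ish random curve on the reference grid."""
    steps = rng.normal(0, scale / 8, T.size)
    return np.cumsum(steps) - steps[0]


class TestWindowMin:
    def test_returns_most_negative_in_window(self):
        curve = -18.4 * np.sin(np.pi * T / 700.0)
        peak = peak_window_min(T, curve, EVENTS)
        assert peak.value == pytest.approx(curve[T == 350][0])
        assert peak.time == 350.0

    def test_exclusively_positive_curve_returns_least_positive(self):
        curve = 2.1 + 3.0 * np.sin(np.pi * T / 850.0) ** 2
        peak = peak_window_min(T, curve, EVENTS)
        assert peak.value == pytest.approx(2.1)

    def test_tie_broken_by_earliest_time(self):
        curve = np.zeros_like(T)
        curve[T == 300] = -5.0
        curve[T == 350] = -5.0
        peak = peak_window_min(T, curve, EVENTS)
        assert peak.time == 300.0

    def test_matches_brute_force_on_100_random_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            curve = random_curve(rng)
            peak = peak_window_min(T, curve, EVENTS)
            v, t = brute_force_min(T, curve, EVENTS)
            assert peak.value == v and peak.time == t

    @given(st.integers(0, 10_000))
    def test_minimality_property(self, seed):
        curve = random_curve(np.random.default_rng(seed))
        peak = peak_window_min(T, curve, EVENTS)
        in_window = (T >= EVENTS.qrs1) & (T <= EVENTS.avc)
        assert np.all(peak.value <= curve[in_window])


class TestEchopacRule:
    @pytest.mark.parametrize(
        "n_val, p_val, expected",
        [(-10.0, 8.0, 8.0), (-10.0, 7.0, -10.0), (-10.0, 7.5, -10.0)],
        ids=["positive-wins", "negative-wins", "exact-75pct-not-exceeded"],
    )
    def test_75_percent_rule(self, n_val, p_val, expected):
        curve = np.zeros_like(T)
        curve[T == 200] = n_val
        curve[T == 300] = p_val
        assert peak_echopac(T, curve, EVENTS).value == pytest.approx(expected)

    def test_monotone_negative_curve_returns_minimum(self):
        # no positive samples at all: P = -1 never beats 0.75*|N|
        curve = np.linspace(-1.0, -15.0, T.size)
        assert peak_echopac(T, curve, EVENTS).value == pytest.approx(
            brute_force_echopac(T, curve, EVENTS)
        )

    def test_no_negative_samples_returns_positive_peak(self):
        curve = 1.0 + np.abs(np.sin(T / 90.0))
        peak = peak_echopac(T, curve, EVENTS)
        assert peak.value == pytest.approx(brute_force_echopac(T, curve, EVENTS))
        assert peak.value > 1.0

    def test_matches_branch_oracle_on_100_random_curves(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            curve = random_curve(rng)
            assert peak_echopac(T, curve, EVENTS).value == brute_force_echopac(
                T, curve, EVENTS
            )

    @given(st.integers(0, 10_000))
    def test_agrees_with_window_min_below_threshold(self, seed):
        """The two rules coincide whenever P <= 0.75 |N| (with N < 0)."""
        curve = random_curve(np.random.default_rng(seed))
        in_window = (T >= EVENTS.qrs1) & (T <= EVENTS.avc)
        n_val = curve[in_window].min()
        p_val = curve[in_window].max()
        if n_val < 0 and p_val <= 0.75 * abs(n_val):
            assert (
                peak_echopac(T, curve, EVENTS).value
                == peak_window_min(T, curve, EVENTS).value
            )


def _trace_from_peaks(peak_values):
    # sin^2 rises to 1 exactly at the on-grid AVC sample (380 ms), so each
    # segment attains its prescribed peak value there; linear recovery after
    segs = {
        lab: np.where(T <= 380, val * np.sin(np.pi * T / 760.0) ** 2, val * (1 - (T - 380) / 470.0))
        for lab, val in zip(aha18_labels(), peak_values)
    }
    return StrainTrace(
        time=T, segments=segs, segment_model=SegmentModel.AHA18
    )


class TestGls:
    def test_mean_of_identical_peaks(self):
        res = compute_gls(_trace_from_peaks([-20.0] * 18), EVENTS)
        assert res.gls == pytest.approx(-20.0)
        assert res.n_segments == 18

    def test_mean_of_two_groups(self):
        res = compute_gls(_trace_from_peaks([-10.0] * 9 + [-20.0] * 9), EVENTS)
        assert res.gls == pytest.approx(-15.0)

    def test_permutation_invariance(self):
        vals = list(np.linspace(-25, -8, 18))
        r1 = compute_gls(_trace_from_peaks(vals), EVENTS)
        r2 = compute_gls(_trace_from_peaks(vals[::-1]), EVENTS)
        assert r1.gls == pytest.approx(r2.gls)

    def test_linear_under_uniform_scaling(self):
        vals = np.linspace(-25, -8, 18)
        r1 = compute_gls(_trace_from_peaks(vals), EVENTS)
        r2 = compute_gls(_trace_from_peaks(2.0 * vals), EVENTS)
        assert r2.gls == pytest.approx(2.0 * r1.gls)

    def test_exclusions_and_qc_flag(self):
        trace = _trace_from_peaks(list(np.linspace(-25, -8, 18)))
        drop = tuple(trace.labels[:3])
        with pytest.warns(UserWarning, match="excluded"):
            res = compute_gls(trace, EVENTS, exclude=drop)
        assert res.qc_flag and res.n_segments == 15
        res2 = compute_gls(trace, EVENTS, exclude=drop[:2])
        assert not res2.qc_flag

    def test_unknown_exclusion_listed(self):
        with pytest.raises(UsageError, match="nonexistent"):
            compute_gls(_trace_from_peaks([-20.0] * 18), EVENTS, exclude=("nonexistent",))

    def test_six_segment_trace_rejected(self):
        segs = {f"s{i}": np.sin(T / 100) for i in range(6)}
        trace = StrainTrace(time=T, segments=segs, segment_model=SegmentModel.SIX)
        with pytest.raises(UsageError, match="18-segment"):
            compute_gls(trace, EVENTS)


class TestStrainRate:
    @staticmethod
    def _trace(values):
        segs = {f"s{i}": values for i in range(6)}
        return StrainTrace(time=T, segments=segs, segment_model=SegmentModel.SIX)

    def test_constant_strain_gives_zero_rate(self):
        sr = strain_rate_from_strain(self._trace(np.full(T.size, -12.0)))
        np.testing.assert_allclose(sr.segments["s0"], 0.0, atol=1e-15)

    def test_linear_ramp_slope(self):
        # -20 % over 400 ms is -0.5 1/s in fractional strain per second
        sr = strain_rate_from_strain(self._trace(-20.0 / 400.0 * T))
        np.testing.assert_allclose(sr.segments["s0"], -0.5, rtol=1e-9)

    def test_sinusoid_matches_analytic_derivative(self):
        # strain = A sin(w t); d(strain/100)/dt_s = A w 1000/100 cos(w t)
        A, w = -15.0, 2 * np.pi / 850.0  # per ms
        sr = strain_rate_from_strain(self._trace(A * np.sin(w * T)))
        analytic = A / 100.0 * w * 1000.0 * np.cos(w * T)
        # central differences are O(h^2); h = 10 ms, w h ~ 0.074
        np.testing.assert_allclose(
            sr.segments["s0"][1:-1], analytic[1:-1], atol=2e-3 * abs(A * w * 10)
        )

    def test_integration_recovers_strain(self):
        from scipy.integrate import cumulative_trapezoid

        values = -18.0 * np.sin(np.pi * T / 850.0) ** 2
        sr = strain_rate_from_strain(self._trace(values))
        recovered = 100.0 * cumulative_trapezoid(
            sr.segments["s0"], T / 1000.0, initial=0.0
        )
        np.testing.assert_allclose(recovered, values - values[0], atol=0.05)

    def test_rejects_strain_rate_input(self):
        sr = strain_rate_from_strain(self._trace(np.sin(T / 100)))
        with pytest.raises(UsageError):
            strain_rate_from_strain(sr)
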