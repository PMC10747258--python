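"""Double-ACF interval estimator: ACF math, peak logic, tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dopplerfhr as d
from dopplerfhr.frri import DegenerateSeriesError
from dopplerfhr.preprocessing import IntegratedSpectrum


def acf_bruteforce(y, max_lag):
    """Independent double-loop evaluation of the normalized ACF."""
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    denom = sum((yi - ybar) ** 2 for yi in y)
    out = []
    for k in range(max_lag + 1):
        num = 0.0
        for i in range(len(y) - k):
            num += (y[i] - ybar) * (y[i + k] - ybar)
        out.append(num / denom)
    return np.array(out)


class TestAcf:
    def test_hand_value_1234(self):
        a = d.acf(np.array([1.0, 2.0, 3.0, 4.0]), max_lag=3)
        assert a.values[0] == pytest.approx(1.0)
        assert a.values[1] == pytest.approx(0.25)  # 1.25 / 5

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(8, 65)
            y = rng.normal(size=n)
            a = d.acf(y, max_lag=n - 1)
            assert np.max(np.abs(a.values - acf_bruteforce(y, n - 1))) < 1e-10

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=4,
            max_size=40,
        )
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_bounded_by_one_property(self, ys):
        y = np.asarray(ys)
        if np.sum((y - y.mean()) ** 2) == 0:  # constant or underflowing spread
            return
        a = d.acf(y, max_lag=len(y) - 1)
        assert np.all(np.abs(a.values) <= 1.0 + 1e-12)
        assert a.values[0] == pytest.approx(1.0)

    def test_sinusoid_peak_at_period(self):
        dt = 0.001
        period = 0.4
        t = np.arange(0, 4 * period, dt)
        a = d.acf(np.sin(2 * np.pi * t / period), max_lag=len(t) - 1, dt=dt)
        peak = d.find_max_peak(a, 0.25, 1.2)
        assert abs(peak - period) <= dt

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            d.acf(np.full(10, 2.0), max_lag=5)


def _acf_from_values(values, dt=0.001):
    return d.AcfSeries(lags=np.arange(len(values)) * dt, values=np.asarray(values))


def _two_peak_acf(l1=0.4, l2=0.8, v1=0.9, v2=1.0, dt=0.001, span=1.3):
    """Synthetic ACF with local maxima of heights v1 at l1 and v2 at l2."""
    lags = np.arange(0, span, dt)
    vals = np.zeros_like(lags)
    for center, height in ((l1, v1), (l2, v2)):
        vals += height * np.exp(-0.5 * ((lags - center) / 0.02) ** 2)
    vals[0] = 1.0
    return d.AcfSeries(lags=lags, values=vals)


class TestPeakSearch:
    def test_highest_local_max_selected(self):
        a = _two_peak_acf(v1=0.9, v2=0.5)
        assert d.find_max_peak(a, 0.25, 1.2) == pytest.approx(0.4, abs=1e-3)

    def test_strictly_decreasing_yields_none(self):
        a = _acf_from_values(np.linspace(1.0, 0.0, 800))
        assert d.find_max_peak(a, 0.25, 0.7) is None

    def test_search_range_respected(self):
        a = _two_peak_acf(v1=0.9, v2=0.5)
        assert d.find_max_peak(a, 0.6, 1.2) == pytest.approx(0.8, abs=1e-3)


class TestHarmonicResolution:
    def test_strong_submultiple_wins(self):
        a = _two_peak_acf(l1=0.4, l2=0.8, v1=0.9, v2=1.0)
        peak = d.find_max_peak(a, 0.25, 1.2)
        assert peak == pytest.approx(0.8, abs=1e-3)
        resolved = d.resolve_harmonic(a, peak, 0.25, 1.2)
        assert resolved == pytest.approx(0.4, abs=1e-3)

    def test_weak_submultiple_ignored(self):
        a = _two_peak_acf(l1=0.4, l2=0.8, v1=0.3, v2=1.0)
        resolved = d.resolve_harmonic(a, 0.8, 0.25, 1.2)
        assert resolved == pytest.approx(0.8, abs=1e-3)

    def test_no_candidate_returns_peak(self):
        a = _two_peak_acf(l1=0.4, l2=0.8, v1=0.0, v2=1.0)
        assert d.resolve_harmonic(a, 0.8, 0.25, 1.2) == pytest.approx(0.8, abs=1e-3)


class TestEstimateWindow:
    def test_resized_window_follows_approximate_interval(self, clean_constant):
        _, _, integ = clean_constant
        est = d.estimate_window(integ, 5.0)
        assert est.ok
        assert est.s_new == pytest.approx(2.5 * est.frri_app)
        assert est.s_new == pytest.approx(1.0, abs=0.05)  # 2 * 0.4 + 0.2

    def test_clean_constant_recovered_within_5ms(self, clean_constant):
        _, _, integ = clean_constant
        for t0 in (0.0, 10.0, 30.0):
            est = d.estimate_window(integ, t0)
            assert est.ok
            assert abs(est.frri_est - 0.4) <= 0.005

    def test_refined_estimate_within_range_of_approximate(self, clean_constant):
        _, _, integ = clean_constant
        cfg = d.FrriSearchConfig()
        est = d.estimate_window(integ, 12.0, cfg)
        assert est.ok
        assert est.frri_app - cfg.range_s <= est.frri_est <= est.frri_app + cfg.range_s

    def test_window_past_end_rejected(self, clean_constant):
        _, _, integ = clean_constant
        with pytest.raises(ValueError):
            d.estimate_window(integ, 59.0)

    def test_constant_window_not_ok(self):
        integ = IntegratedSpectrum(
            values=np.full(5000, 1.0), times=np.arange(5000) * 1e-3, source_fs=1000.0
        )
        est = d.estimate_window(integ, 0.0)
        assert not est.ok
        assert np.isnan(est.frri_est)


class TestTrack:
    def test_constant_rate_window_advance_and_count(self, clean_constant):
        _, _, integ = clean_constant
        ests = d.track(integ)
        assert 250 <= len(ests) <= 300  # ~ (60 - 3.75) / 0.2
        starts = np.array([e.window_start for e in ests])
        assert np.allclose(np.diff(starts), 0.2, atol=0.01)

    def test_deterministic(self, clean_constant):
        _, _, integ = clean_constant
        a = d.track(integ)
        b = d.track(integ)
        assert [e.frri_est for e in a] == [e.frri_est for e in b]

    def test_sinusoidal_tracking_follows_local_gap(self, clean_sinusoidal):
        sched, _, integ = clean_sinusoidal
        ests = [e for e in d.track(integ) if e.ok]
        ref = np.array([e.window_start + e.s_new / 2.0 for e in ests])
        frri = np.array([e.frri_est for e in ests])
        est, true = d.pair_with_truth(ref, frri, sched)
        assert np.mean(np.abs(est - true)) <= 0.015

    def test_series_shorter_than_window_rejected(self):
        integ = IntegratedSpectrum(
            values=np.random.default_rng(0).random(1000),
            times=np.arange(1000) * 1e-3,
            source_fs=1000.0,
        )
        with pytest.raises(ValueError):
            d.track(integ)
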