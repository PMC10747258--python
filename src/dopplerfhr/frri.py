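"""Beat-to-beat fetal RR-interval (FRRI) estimation by double autocorrelation.

The integrated-spectrum envelope is quasi-periodic at the fetal cardiac
period.  Each analysis window is processed in two passes:

1. A fixed window of length ``S`` (default 3.75 s, the span standard in
   computerized fetal non-stress-test analysis) yields an autocorrelation
   whose highest peak inside the physiological lag range gives an
   approximate interval ``frri_app``; a harmonic check replaces the peak by
   a strong sub-multiple if one exists, so an integer multiple of the true
   period is not mistaken for it.
2. The window is resized to ``S_new = 2 * frri_app + delta_factor * frri_app``
   (just over two cardiac cycles) and the autocorrelation is recomputed; the
   highest peak within ``frri_app ± range`` is the refined estimate
   ``frri_est``.

Windows then advance by half the previous refined interval, so roughly two
estimates are produced per heartbeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .preprocessing import IntegratedSpectrum


class DegenerateSeriesError(ValueError):
    """Raised when the autocorrelation of a constant series is requested."""


@dataclass(frozen=True)
class AcfSeries:
    """Normalized autocorrelation values on a uniform lag grid."""

    lags: np.ndarray    # seconds, starting at 0
    values: np.ndarray  # dimensionless, values[0] == 1

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])

    def value_at(self, lag: float) -> float:
        return float(self.values[int(round(lag / self.dt))])


@dataclass(frozen=True)
class FrriSearchConfig:
    """Tunables of the double-ACF search.

    ``frri_min``/``frri_max`` bracket the physiological fetal range
    (240 down to 50 bpm); ``range_s`` constrains how far the refined
    estimate may move from the approximate one; ``harmonic_alpha`` is the
    minimum ACF-value ratio at which a sub-multiple peak supersedes the
    maximum peak.
    """

    S: float = 3.75
    frri_min: float = 0.25
    frri_max: float = 1.2
    range_s: float = 0.1
    delta_factor: float = 0.5
    harmonic_alpha: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.frri_min < self.frri_max < self.S:
            raise ValueError("need 0 < frri_min < frri_max < S")
        if self.range_s <= 0:
            raise ValueError("range_s must be positive")


@dataclass(frozen=True)
class FrriEstimate:
    """One window's approximate and refined interval estimates."""

    window_start: float  # s
    frri_app: float      # s (NaN when pass 1 found no peak)
    s_new: float         # s (NaN when pass 1 found no peak)
    frri_est: float      # s (equals frri_app when pass 2 found no peak)
    ok: bool


def resized_window_len(frri_app: float, delta_factor: float = 0.5) -> float:
    """Pass-2 window length: two beat intervals plus a guard of
    ``delta_factor * frri_app`` (default half an interval)."""
    return 2.0 * frri_app + delta_factor * frri_app


def acf(y: np.ndarray, max_lag: int, dt: float = 1.0) -> AcfSeries:
    """Normalized autocorrelation of ``y`` for lags ``0..max_lag``.

    Mean-subtracted, with the full-series sum of squares as denominator:
    ``acf_k = sum_{i<=N-k} (y_i - ybar)(y_{i+k} - ybar) / sum (y_i - ybar)^2``.
    By Cauchy–Schwarz every value lies in [-1, 1] and ``acf_0 = 1``.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("series must have length >= 2")
    d = y - y.mean()
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise DegenerateSeriesError("constant series has undefined autocorrelation")
    max_lag = int(min(max_lag, y.size - 1))
    r = _sig.correlate(d, d, mode="full", method="auto")[y.size - 1 : y.size + max_lag]
    return AcfSeries(lags=np.arange(max_lag + 1) * dt, values=r / denom)


def find_max_peak(a: AcfSeries, lo: float, hi: float) -> float | None:
    """Lag of the highest strict local maximum with ``lo <= lag <= hi``.

    Ties break toward the smaller lag (favoring the fundamental); returns
    ``None`` when no interior local maximum exists in the range.
    """
    v = a.values
    interior = np.zeros(v.size, dtype=bool)
    interior[1:-1] = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    sel = interior & (a.lags >= lo) & (a.lags <= hi)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return None
    best = idx[np.argmax(v[idx])]  # argmax returns first occurrence: smaller lag
    return float(a.lags[best])


def resolve_harmonic(
    a: AcfSeries,
    peak: float,
    lo: float,
    hi: float,
    range_s: float = 0.1,
    alpha: float = 0.75,
) -> float:
    """Replace a peak by a strong sub-multiple until stable.

    If a local maximum exists within ``peak/2 ± range_s/2`` (inside
    ``[lo, hi]``) whose ACF value is at least ``alpha`` times the peak's,
    the peak is assumed to be a harmonic of that shorter period.
    """
    while True:
        cand_lo = max(peak / 2.0 - range_s / 2.0, lo)
        cand_hi = min(peak / 2.0 + range_s / 2.0, hi)
        if cand_lo >= cand_hi:
            return peak
        cand = find_max_peak(a, cand_lo, cand_hi)
        if cand is None or a.value_at(cand) < alpha * a.value_at(peak):
            return peak
        peak = cand


def estimate_window(
    s: IntegratedSpectrum, t0: float, cfg: FrriSearchConfig = FrriSearchConfig()
) -> FrriEstimate:
    """Two-pass interval estimate for the window starting at ``t0``.

    The resized pass-2 window stays anchored at ``t0`` (it replaces the
    pass-1 window in place).  A window where either pass finds no usable
    peak is flagged ``ok=False``; pass-2 failures carry ``frri_app`` as the
    estimate so the tracker can still advance.
    """
    if t0 + cfg.S > s.times[-1] + s.step + 1e-9:
        raise ValueError("window extends past the end of the series")
    dt = s.step

    def _peak(seg: np.ndarray, lo: float, hi: float) -> tuple[AcfSeries, float] | None:
        try:
            a = acf(seg, max_lag=int(round(hi / dt)) + 1, dt=dt)
        except DegenerateSeriesError:
            return None
        p = find_max_peak(a, lo, hi)
        return None if p is None else (a, p)

    res = _peak(s.segment(t0, t0 + cfg.S), cfg.frri_min, cfg.frri_max)
    if res is None:
        return FrriEstimate(t0, float("nan"), float("nan"), float("nan"), False)
    a1, p1 = res
    frri_app = resolve_harmonic(
        a1, p1, cfg.frri_min, cfg.frri_max, cfg.range_s, cfg.harmonic_alpha
    )
    s_new = resized_window_len(frri_app, cfg.delta_factor)

    res2 = _peak(
        s.segment(t0, t0 + s_new),
        max(frri_app - cfg.range_s, dt),
        frri_app + cfg.range_s,
    )
    if res2 is None:
        return FrriEstimate(t0, frri_app, s_new, frri_app, False)
    return FrriEstimate(t0, frri_app, s_new, res2[1], True)


def track(
    s: IntegratedSpectrum, cfg: FrriSearchConfig = FrriSearchConfig()
) -> list[FrriEstimate]:
    """Slide the two-pass estimator across the whole series.

    Each window starts where the previous start plus half the previous
    refined interval lands (``frri_app / 2`` when refinement failed,
    ``S / 2`` when no peak was found at all); every window begins a fresh
    pass-1 at length ``S``.  Stops when a full ``S`` window no longer fits.
    """
    t_end = float(s.times[-1]) + s.step
    if t_end - float(s.times[0]) < cfg.S:
        raise ValueError("series shorter than one analysis window")
    out: list[FrriEstimate] = []
    t0 = float(s.times[0])
    while t0 + cfg.S <= t_end + 1e-9:
        est = estimate_window(s, t0, cfg)
        out.append(est)
        if np.isfinite(est.frri_est):
            t0 += est.frri_est / 2.0
        elif np.isfinite(est.frri_app):
            t0 += est.frri_app / 2.0
        else:
            t0 += cfg.S / 2.0
    return out


def estimates_to_frame(estimates: list[FrriEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_start_s": [e.window_start for e in estimates],
            "frri_app_s": [e.frri_app for e in estimates],
            "s_new_s": [e.s_new for e in estimates],
            "frri_est_s": [e.frri_est for e in estimates],
            "ok": [e.ok for e in estimates],
        }
    )


def write_estimates_csv(path: str | Path, estimates: list[FrriEstimate]) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def read_estimates_csv(path: str | Path) -> list[FrriEstimate]:
    df = pd.read_csv(path)
    return [
        FrriEstimate(
            float(r.window_start_s),
            float(r.frri_app_s),
            float(r.s_new_s),
            float(r.frri_est_s),
            bool(r.ok),
        )
        for r in df.itertuples()
    ]
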