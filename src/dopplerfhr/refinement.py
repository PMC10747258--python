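"""SQI-adaptive Kalman refinement of rough beat-interval estimates.

The beat-interval series is modeled as a first-order autoregressive process
with a unit state-transition coefficient: state x_m = x_{m-1} + w,
measurement z_m = x_m + v, with w ~ N(0, Q) and v ~ N(0, R).  Two scalar
Kalman filters run in cascade:

1. a conventional filter with fixed noise covariances (R0 = 1, Q0 = 0.1)
   smooths the rough estimates;
2. an adaptive filter (R0 = 1, Q0 = 1) whose per-step measurement noise is
   inflated from the segment's combined SQI,

       R_m = R0 * exp(1 / SQI_m^2 - 1),

   so a low-quality measurement is nearly ignored (gain -> 0) while a
   perfect-quality one is trusted at R0.

Finally, estimates arising from long runs of low-quality segments (SQI
strictly below the 8th decile, run length >= 4, i.e. "more than three
consecutive") are discarded outright — such stretches cannot be corrected,
only removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: exponent cap keeping exp() finite; exp(700) ~ 1e304 already forces the
#: Kalman gain to ~0, realizing the intended "measurement ignored" limit
_EXP_CAP = 700.0


@dataclass(frozen=True)
class KalmanConfig:
    """Scalar Kalman filter settings.

    ``r0``/``q0`` are the measurement/process noise covariances; ``x0``
    defaults to the first measurement (avoiding transient bias) and ``p0``
    to 1.  ``sqi_floor`` caps the adaptive-noise singularity at SQI = 0.
    """

    r0: float = 1.0
    q0: float = 0.1
    x0: float | None = None
    p0: float = 1.0
    sqi_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.q0 <= 0 or self.p0 <= 0:
            raise ValueError("r0, q0 and p0 must be positive")


@dataclass(frozen=True)
class RefinedTrace:
    """Aligned raw, smoothed and refined interval series with kept flags."""

    times: np.ndarray      # s
    frri_raw: np.ndarray   # s
    frri_kf1: np.ndarray   # s, after the fixed-noise filter
    frri_kf2: np.ndarray   # s, after the SQI-adaptive filter
    sqi: np.ndarray        # [0, 1]
    kept: np.ndarray       # bool


def adapt_R(sqi: float | np.ndarray, r0: float = 1.0, floor: float = 1e-3) -> np.ndarray:
    """Measurement-noise covariance inflated by signal quality.

    ``R = r0 * exp(1 / max(sqi, floor)^2 - 1)``; equals ``r0`` at SQI 1 and
    grows astronomically (but stays finite, via exponent capping) as SQI
    approaches 0.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    s = np.maximum(np.asarray(sqi, dtype=float), floor)
    return r0 * np.exp(np.minimum(1.0 / s**2 - 1.0, _EXP_CAP))


def kalman(
    z: np.ndarray, cfg: KalmanConfig = KalmanConfig(), R_series: np.ndarray | None = None
) -> np.ndarray:
    """Scalar Kalman filter over measurement series ``z``.

    Per step: predict ``x- = x``, ``P- = P + q0``; gain ``K = P- / (P- + R_m)``;
    update ``x = x- + K (z_m - x-)``, ``P = (1 - K) P-``.  ``R_m`` is
    ``cfg.r0`` for every step unless ``R_series`` supplies per-step values.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty measurement series")
    if R_series is not None:
        R_series = np.asarray(R_series, dtype=float)
        if R_series.shape != z.shape:
            raise ValueError("R_series must match z in length")
    x = float(z[0]) if cfg.x0 is None else float(cfg.x0)
    p = cfg.p0
    out = np.empty_like(z)
    for m in range(z.size):
        p_pred = p + cfg.q0
        r = cfg.r0 if R_series is None else R_series[m]
        k = p_pred / (p_pred + r)
        x = x + k * (z[m] - x)
        p = (1.0 - k) * p_pred
        out[m] = x
    return out


def discard_runs(sqi: np.ndarray, quantile: float = 0.8, run_len: int = 4) -> np.ndarray:
    """Kept flags: drop maximal runs of >= ``run_len`` low-quality estimates.

    "Low quality" means SQI strictly below the ``quantile`` decile of the
    whole series; shorter low runs are retained (the adaptive filter can
    still correct them).
    """
    sqi = np.asarray(sqi, dtype=float)
    if sqi.size == 0:
        raise ValueError("empty SQI series")
    low = sqi < np.quantile(sqi, quantile)
    kept = np.ones(sqi.size, dtype=bool)
    i = 0
    while i < sqi.size:
        if low[i]:
            j = i
            while j < sqi.size and low[j]:
                j += 1
            if j - i >= run_len:
                kept[i:j] = False
            i = j
        else:
            i += 1
    return kept


def refine(
    times: np.ndarray,
    frri_raw: np.ndarray,
    sqi: np.ndarray,
    stage1: KalmanConfig = KalmanConfig(r0=1.0, q0=0.1),
    stage2: KalmanConfig = KalmanConfig(r0=1.0, q0=1.0),
    cascade: bool = True,
    discard_quantile: float = 0.8,
    discard_run_len: int = 4,
) -> RefinedTrace:
    """Two-stage Kalman refinement plus low-quality-run discarding.

    Stage 2 consumes stage-1 output by default (``cascade=True``); set
    ``cascade=False`` to run the adaptive filter on the raw series instead.
    """
    times = np.asarray(times, dtype=float)
    frri_raw = np.asarray(frri_raw, dtype=float)
    sqi = np.asarray(sqi, dtype=float)
    if not times.shape == frri_raw.shape == sqi.shape:
        raise ValueError("times, frri_raw and sqi must have equal length")
    kf1 = kalman(frri_raw, stage1)
    r_series = adapt_R(sqi, stage2.r0, stage2.sqi_floor)
    kf2 = kalman(kf1 if cascade else frri_raw, stage2, R_series=r_series)
    kept = discard_runs(sqi, discard_quantile, discard_run_len)
    return RefinedTrace(
        times=times, frri_raw=frri_raw, frri_kf1=kf1, frri_kf2=kf2, sqi=sqi, kept=kept
    )
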