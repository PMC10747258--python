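"""Evaluation metrics and the scenario-comparison harness.

Converts beat intervals to heart rates (FHR = 60 / FRRI with FRRI in
seconds), pairs per-window estimates with ground-truth beat annotations,
and computes three figures of merit:

* RMSE of the beat interval in milliseconds,
* AAE — averaged absolute FHR error in beats per minute,
* coverage — percentage of emitted interval estimates retained after
  quality-based discarding.

The harness compares four processing scenarios sharing one set of rough
estimates: raw estimation only, removing low-SQI estimates, conventional
Kalman smoothing, and the full SQI-adaptive refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frri import FrriSearchConfig, track
from .preprocessing import preprocess
from .recording import BeatSchedule, DusRecording
from .refinement import refine
from .sqa import SignalQualityAssessor, align_sqi, segment_for_sqa


def frri_to_fhr(frri: float | np.ndarray) -> float | np.ndarray:
    """Fetal heart rate in bpm from a beat interval in seconds."""
    frri = np.asarray(frri, dtype=float)
    if np.any(frri <= 0):
        raise ValueError("beat interval must be positive")
    out = 60.0 / frri
    return float(out) if out.ndim == 0 else out


def fhr_to_frri(fhr: float | np.ndarray) -> float | np.ndarray:
    """Beat interval in seconds from a heart rate in bpm."""
    fhr = np.asarray(fhr, dtype=float)
    if np.any(fhr <= 0):
        raise ValueError("heart rate must be positive")
    out = 60.0 / fhr
    return float(out) if out.ndim == 0 else out


def nae(frri_est: float, frri_true: float) -> float:
    """Normalized absolute error ``|est - true| / true``.

    Values above 0.03 serve as a proxy label for a low-quality segment.
    """
    if frri_true <= 0:
        raise ValueError("true beat interval must be positive")
    return abs(frri_est - frri_true) / frri_true


def pair_with_truth(
    ref_times: np.ndarray,
    frri_est: np.ndarray,
    truth: BeatSchedule,
    mode: str = "containing",
) -> tuple[np.ndarray, np.ndarray]:
    """Match each estimate to the ground-truth gap at its reference time.

    ``mode="containing"`` (default) takes the inter-beat gap containing the
    reference time; ``mode="nearest-midpoint"`` takes the gap whose midpoint
    is closest.  Estimates whose reference time falls outside the annotated
    span are dropped.  Returns aligned (estimate, truth) interval arrays.
    """
    bt = truth.beat_times
    if bt.size < 2:
        raise ValueError("ground truth needs at least two beats")
    ref_times = np.asarray(ref_times, dtype=float)
    frri_est = np.asarray(frri_est, dtype=float)
    gaps = np.diff(bt)
    if mode == "containing":
        idx = np.searchsorted(bt, ref_times, side="right") - 1
        valid = (idx >= 0) & (idx < gaps.size)
    elif mode == "nearest-midpoint":
        mids = bt[:-1] + gaps / 2.0
        idx = np.clip(np.searchsorted(mids, ref_times), 0, mids.size - 1)
        left = np.clip(idx - 1, 0, mids.size - 1)
        idx = np.where(
            np.abs(mids[left] - ref_times) <= np.abs(mids[idx] - ref_times), left, idx
        )
        valid = np.ones(ref_times.size, dtype=bool)
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    valid &= np.isfinite(frri_est)
    return frri_est[valid], gaps[idx[valid]]


@dataclass(frozen=True)
class MetricsReport:
    """RMSE (ms, over intervals), AAE (bpm, over rates), coverage (%)."""

    rmse_ms: float
    aae_bpm: float
    coverage_pct: float
    n_pairs: int


def metrics(
    est_frri: np.ndarray, true_frri: np.ndarray, n_kept: int, n_total: int
) -> MetricsReport:
    """Error metrics over paired kept estimates plus retention coverage."""
    est_frri = np.asarray(est_frri, dtype=float)
    true_frri = np.asarray(true_frri, dtype=float)
    if est_frri.shape != true_frri.shape:
        raise ValueError("paired series must have equal length")
    coverage = 100.0 * n_kept / n_total if n_total else 0.0
    if est_frri.size == 0:
        return MetricsReport(float("nan"), float("nan"), coverage, 0)
    rmse_ms = float(np.sqrt(np.mean((est_frri - true_frri) ** 2))) * 1000.0
    aae_bpm = float(np.mean(np.abs(60.0 / est_frri - 60.0 / true_frri)))
    return MetricsReport(rmse_ms, aae_bpm, coverage, int(est_frri.size))


@dataclass
class ScenarioOutcome:
    """Per-scenario metrics plus the shared intermediate series."""

    reports: dict[str, MetricsReport]
    times: np.ndarray       # window starts, s
    ref_times: np.ndarray   # pairing reference times, s
    frri_raw: np.ndarray    # s
    frri_kf1: np.ndarray    # s
    frri_kf2: np.ndarray    # s
    sqi: np.ndarray
    kept_s3: np.ndarray
    kept_s5: np.ndarray


SCENARIO_NAMES = ("fhr_only", "remove_unreliable", "conventional_kf", "proposed")


def run_scenarios(
    rec: DusRecording,
    cfg: FrriSearchConfig = FrriSearchConfig(),
    assessor: SignalQualityAssessor | None = None,
    pairing: str = "containing",
    discard_quantile: float = 0.8,
    discard_run_len: int = 4,
) -> ScenarioOutcome:
    """Run the four implemented comparison scenarios on one recording.

    All scenarios share the pre-processing, the rough double-ACF interval
    estimates and the SQI series:

    * ``fhr_only`` — rough estimates, everything kept;
    * ``remove_unreliable`` — drop every estimate whose SQI is strictly
      below the 8th decile of all SQIs;
    * ``conventional_kf`` — fixed-noise Kalman smoothing, everything kept;
    * ``proposed`` — cascade of fixed and SQI-adaptive Kalman filters with
      low-quality-run discarding.

    ``assessor`` may be a fitted quality model, an unfitted one (it is then
    trained on this recording's own segments — the default protocol),
    or ``None`` to train a default model.  The recording must carry beat
    annotations.
    """
    if rec.annotations is None or rec.annotations.beat_times.size < 2:
        raise ValueError("recording must carry ground-truth beat annotations")
    integ = preprocess(rec)
    estimates = [e for e in track(integ, cfg) if np.isfinite(e.frri_est)]
    if not estimates:
        raise ValueError("no usable interval estimates")
    times = np.array([e.window_start for e in estimates])
    frri_raw = np.array([e.frri_est for e in estimates])
    ref_times = np.array([e.window_start + e.s_new / 2.0 for e in estimates])

    segments = segment_for_sqa(integ, times)
    if assessor is None:
        assessor = SignalQualityAssessor(vae_epochs=30, som_iterations=3000, seed=0)
    if not hasattr(assessor, "som_"):
        assessor.fit(np.stack([s.x for s in segments]))
    records = assessor.score_segments(segments)
    sqi = align_sqi(times, np.array([r.start for r in records]), np.array([r.sqi for r in records]))

    trace = refine(
        times,
        frri_raw,
        sqi,
        discard_quantile=discard_quantile,
        discard_run_len=discard_run_len,
    )
    kept_s3 = sqi >= np.quantile(sqi, discard_quantile)
    n = len(estimates)

    def report(series: np.ndarray, kept: np.ndarray) -> MetricsReport:
        est, true = pair_with_truth(ref_times[kept], series[kept], rec.annotations, pairing)
        return metrics(est, true, int(kept.sum()), n)

    all_kept = np.ones(n, dtype=bool)
    reports = {
        "fhr_only": report(frri_raw, all_kept),
        "remove_unreliable": report(frri_raw, kept_s3),
        "conventional_kf": report(trace.frri_kf1, all_kept),
        "proposed": report(trace.frri_kf2, trace.kept),
    }
    return ScenarioOutcome(
        reports=reports,
        times=times,
        ref_times=ref_times,
        frri_raw=frri_raw,
        frri_kf1=trace.frri_kf1,
        frri_kf2=trace.frri_kf2,
        sqi=sqi,
        kept_s3=kept_s3,
        kept_s5=trace.kept,
    )
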