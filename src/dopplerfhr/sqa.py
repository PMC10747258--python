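"""Signal-quality assessment: VAE representations + SOM quantization error.

Quality scoring is unsupervised and rests on one assumption: most segments
of a recording are clean, so low-quality segments are *outliers* in
representation space.  1.2 s integrated-spectrum windows (aligned to the
beat-interval estimator's resized-window starts, resampled to 1024 samples)
are encoded by the VAE; the latent means are quantized by a SOM; and each
segment's quantization error (QE) is mapped to a combined signal-quality
index (SQI) in [0, 1] by a thresholded linear ramp:

    qe_norm = (qe - qe_min) / (qe_max - qe_min)            # min-max, [0, 1]
    sqi     = 1                                 if qe_norm <= th
              1 - (qe_norm - th) / (1 - th)     otherwise

with ``th`` the 90th percentile of normalized training QEs, reflecting the
expectation that roughly 90% of segments are high quality.  Normalization
constants and ``th`` are fit on the training corpus and frozen, so scoring
does not depend on the batch being scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocessing import IntegratedSpectrum
from .som import SelfOrganizingMap
from .vae import ConvVae1d

SEGMENT_WIN = 1.2  # s, the mean resized-window length of the interval estimator
SEGMENT_LEN = 1024


@dataclass(frozen=True)
class SqaSegment:
    """One resampled 1.2 s integrated-spectrum segment."""

    start: float        # s
    raw_len: int        # samples before resampling
    x: np.ndarray       # length SEGMENT_LEN


@dataclass(frozen=True)
class SqiRecord:
    """Quality scores of one segment."""

    start: float
    qe: float
    qe_norm: float
    sqi: float


def segment_for_sqa(
    s: IntegratedSpectrum,
    starts: list[float] | np.ndarray,
    win: float = SEGMENT_WIN,
    n_out: int = SEGMENT_LEN,
) -> list[SqaSegment]:
    """Cut ``[start, start + win)`` windows and resample each to ``n_out``.

    Linear endpoint-preserving resampling; windows extending past the end
    of the series are skipped with a warning (their paired interval
    estimates later reuse the nearest preceding segment's score).
    """
    if win <= 0:
        raise ValueError("win must be positive")
    t_end = float(s.times[-1]) + s.step
    out: list[SqaSegment] = []
    skipped = 0
    for t0 in starts:
        if t0 + win > t_end + 1e-9:
            skipped += 1
            continue
        seg = s.segment(float(t0), float(t0) + win)
        xs = np.linspace(0.0, seg.size - 1.0, n_out)
        out.append(
            SqaSegment(start=float(t0), raw_len=seg.size, x=np.interp(xs, np.arange(seg.size), seg))
        )
    if skipped:
        warnings.warn(f"skipped {skipped} segment(s) extending past the series end")
    return out


def normalize_segments(X: np.ndarray) -> np.ndarray:
    """Per-segment min-max scaling to [0, 1]; constant segments map to 0."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    span = X.max(axis=1, keepdims=True) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def combined_sqi(qes: np.ndarray, th_quantile: float = 0.9) -> list[SqiRecord]:
    """Self-normalized combined SQI of a QE batch.

    Min-max normalizes the QEs, sets ``th`` at the requested quantile of
    the normalized values, and applies the ramp.  Degenerate batches (all
    QEs equal) are all assigned SQI 1.
    """
    qes = np.asarray(qes, dtype=float)
    lo, hi = float(qes.min()), float(qes.max())
    qe_norm = (qes - lo) / (hi - lo) if hi > lo else np.zeros_like(qes)
    th = float(np.quantile(qe_norm, th_quantile))
    sqi = _ramp(qe_norm, th)
    return [
        SqiRecord(start=float("nan"), qe=float(q), qe_norm=float(n), sqi=float(s))
        for q, n, s in zip(qes, qe_norm, sqi)
    ]


def _ramp(qe_norm: np.ndarray, th: float) -> np.ndarray:
    if th >= 1.0:
        return np.ones_like(qe_norm)
    return np.where(qe_norm <= th, 1.0, 1.0 - (qe_norm - th) / (1.0 - th))


def align_sqi(
    window_starts: np.ndarray, seg_starts: np.ndarray, sqi: np.ndarray
) -> np.ndarray:
    """SQI per estimator window: matching segment start, else nearest preceding."""
    window_starts = np.asarray(window_starts, dtype=float)
    seg_starts = np.asarray(seg_starts, dtype=float)
    idx = np.searchsorted(seg_starts, window_starts + 1e-9) - 1
    return np.asarray(sqi, dtype=float)[np.clip(idx, 0, len(seg_starts) - 1)]


class SignalQualityAssessor:
    """VAE + SOM quality model (scikit-learn style estimator).

    ``fit`` trains the VAE on per-segment min-max-normalized segments,
    encodes them to latent means, trains the SOM on those means, and
    freezes the QE normalization constants and the SQI threshold on the
    training corpus.  ``score_samples`` maps new segments to SQIs in
    [0, 1] using the frozen statistics.

    Attributes (after ``fit``)
    --------------------------
    vae_ : ConvVae1d
    som_ : SelfOrganizingMap
    qe_min_, qe_max_ : float       training-corpus QE range
    th_ : float                    SQI ramp threshold on normalized QE
    train_sqi_ : ndarray           SQIs of the training segments
    """

    def __init__(
        self,
        latent_dim: int = 32,
        vae_channels: tuple[int, ...] = (8, 16, 24, 32, 40),
        vae_epochs: int = 100,
        vae_batch_size: int = 64,
        vae_lr: float = 1e-3,
        som_grid: tuple[int, int] = (30, 30),
        som_iterations: int = 15000,
        th_quantile: float = 0.9,
        seed: int = 0,
    ):
        self.latent_dim = latent_dim
        self.vae_channels = vae_channels
        self.vae_epochs = vae_epochs
        self.vae_batch_size = vae_batch_size
        self.vae_lr = vae_lr
        self.som_grid = som_grid
        self.som_iterations = som_iterations
        self.th_quantile = th_quantile
        self.seed = seed

    _param_names = (
        "latent_dim vae_channels vae_epochs vae_batch_size vae_lr "
        "som_grid som_iterations th_quantile seed"
    ).split()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "SignalQualityAssessor":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "SignalQualityAssessor":
        """Train on raw (un-normalized) segments of shape ``(n, 1024)``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty (n_segments, segment_len) array")
        Xn = normalize_segments(X)
        self.vae_ = ConvVae1d(
            latent_dim=self.latent_dim,
            channels=self.vae_channels,
            input_len=X.shape[1],
            epochs=self.vae_epochs,
            batch_size=self.vae_batch_size,
            lr=self.vae_lr,
            seed=self.seed,
        ).fit(Xn)
        mus = self.vae_.transform(Xn)
        self.som_ = SelfOrganizingMap(
            grid=self.som_grid, n_iter=self.som_iterations, seed=self.seed + 1
        ).fit(mus)
        qes = self.som_.quantization_error(mus)
        self.qe_min_, self.qe_max_ = float(qes.min()), float(qes.max())
        qe_norm = self._normalize_qe(qes)
        self.th_ = float(np.quantile(qe_norm, self.th_quantile))
        self.train_sqi_ = _ramp(qe_norm, self.th_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "som_"):
            raise RuntimeError("assessor is not fitted")

    def _normalize_qe(self, qes: np.ndarray) -> np.ndarray:
        span = self.qe_max_ - self.qe_min_
        if span <= 0:
            return np.zeros_like(qes)
        return np.clip((qes - self.qe_min_) / span, 0.0, 1.0)

    def quantization_errors(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        mus = self.vae_.transform(normalize_segments(np.asarray(X, dtype=float)))
        return self.som_.quantization_error(mus)

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Combined SQI in [0, 1] for each segment row of ``X``."""
        qes = self.quantization_errors(X)
        return _ramp(self._normalize_qe(qes), self.th_)

    def score_segments(self, segments: list[SqaSegment]) -> list[SqiRecord]:
        """Score :class:`SqaSegment` objects, keeping their start stamps."""
        X = np.stack([s.x for s in segments])
        qes = self.quantization_errors(X)
        qe_norm = self._normalize_qe(qes)
        sqi = _ramp(qe_norm, self.th_)
        return [
            SqiRecord(start=s.start, qe=float(q), qe_norm=float(n), sqi=float(v))
            for s, q, n, v in zip(segments, qes, qe_norm, sqi)
        ]

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "vae.npz", **self.vae_.state_dict())
        np.savez(d / "som.npz", weights=self.som_.weights_)
        meta = {
            "params": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.get_params().items()
            },
            "qe_min": self.qe_min_,
            "qe_max": self.qe_max_,
            "th": self.th_,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SignalQualityAssessor":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        params = {
            k: tuple(v) if isinstance(v, list) else v for k, v in meta["params"].items()
        }
        obj = cls(**params)
        obj.vae_ = ConvVae1d(
            latent_dim=obj.latent_dim,
            channels=obj.vae_channels,
            epochs=obj.vae_epochs,
            batch_size=obj.vae_batch_size,
            lr=obj.vae_lr,
            seed=obj.seed,
        )
        with np.load(d / "vae.npz") as z:
            obj.vae_.load_state_dict(dict(z))
        obj.som_ = SelfOrganizingMap(
            grid=obj.som_grid, n_iter=obj.som_iterations, seed=obj.seed + 1
        )
        with np.load(d / "som.npz") as z:
            obj.som_.weights_ = z["weights"]
        obj.som_.n_features_in_ = obj.som_.weights_.shape[1]
        obj.qe_min_, obj.qe_max_ = meta["qe_min"], meta["qe_max"]
        obj.th_ = meta["th"]
        return obj
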