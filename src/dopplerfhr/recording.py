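"""Doppler-ultrasound recording container and file I/O.

A fetal Doppler ultrasound (DUS) recording is a single-channel audio-band
signal picked up by an abdominal transducer; fetal cardiac wall and valve
motion modulates it quasi-periodically.  This module holds the in-memory
representation plus readers/writers for the two plain-text/PCM dialects the
toolkit exchanges: 16-bit PCM WAV and one-amplitude-per-row CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


@dataclass(frozen=True)
class BeatSchedule:
    """Ground-truth beat times for a recording.

    Attributes
    ----------
    beat_times : np.ndarray
        Strictly ascending beat instants in seconds.
    pattern : str
        Generating pattern, one of ``{"constant", "sinusoidal", "piecewise"}``.
    base_frri : float
        Nominal beat-to-beat (RR) interval in seconds.
    """

    beat_times: np.ndarray
    pattern: str = "constant"
    base_frri: float = float("nan")

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        if bt.size >= 2 and not np.all(np.diff(bt) > 0):
            raise ValueError("beat_times must be strictly ascending")

    @property
    def intervals(self) -> np.ndarray:
        """Inter-beat gaps in seconds (length ``len(beat_times) - 1``)."""
        return np.diff(self.beat_times)


@dataclass(frozen=True)
class DusRecording:
    """Raw 1-D DUS amplitude series with sampling rate and optional truth.

    Attributes
    ----------
    samples : np.ndarray
        Amplitudes in arbitrary units; all finite.
    fs : float
        Sampling frequency in Hz.
    annotations : BeatSchedule, optional
        Ground-truth beat times, if known (synthetic data or expert marks).
    corruption_mask : np.ndarray of bool, optional
        Per-sample flag marking artifact-corrupted samples.
    """

    samples: np.ndarray
    fs: float
    annotations: BeatSchedule | None = None
    corruption_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", x)
        if self.corruption_mask is not None:
            m = np.asarray(self.corruption_mask, dtype=bool)
            if m.shape != x.shape:
                raise ValueError("corruption_mask must match samples shape")
            object.__setattr__(self, "corruption_mask", m)

    @property
    def duration(self) -> float:
        """Recording length in seconds (``len(samples) / fs``)."""
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray, **kw) -> "DusRecording":
        return replace(self, samples=samples, **kw)


def _normalize_unit(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x)) if x.size else 0.0
    return x / peak if peak > 0 else x


def write_wav(path: str | Path, rec: DusRecording) -> None:
    """Write a recording as 16-bit PCM WAV, peak-normalized to [-1, 1]."""
    x = _normalize_unit(rec.samples)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(round(rec.fs)), pcm)


def read_wav(path: str | Path) -> DusRecording:
    """Read a PCM WAV file into a :class:`DusRecording` (amplitudes in [-1, 1])."""
    fs, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return DusRecording(samples=np.asarray(data, dtype=float), fs=float(fs))


def write_csv(path: str | Path, rec: DusRecording) -> None:
    """Write amplitudes one per row; the header column name encodes fs."""
    pd.DataFrame({f"amplitude_fs{rec.fs:g}": rec.samples}).to_csv(path, index=False)


def read_csv(path: str | Path, fs: float | None = None) -> DusRecording:
    """Read a one-column amplitude CSV.

    The sampling rate is taken from the header (``amplitude_fs<hz>``) when
    present, otherwise from the ``fs`` argument.
    """
    df = pd.read_csv(path)
    col = df.columns[0]
    if fs is None:
        if not col.startswith("amplitude_fs"):
            raise ValueError("fs not given and not encoded in the CSV header")
        fs = float(col.removeprefix("amplitude_fs"))
    return DusRecording(samples=df[col].to_numpy(dtype=float), fs=float(fs))


def write_annotations(path: str | Path, schedule: BeatSchedule) -> None:
    """Write beat times as a CSV with column ``beat_time_s``."""
    pd.DataFrame({"beat_time_s": schedule.beat_times}).to_csv(path, index=False)


def read_annotations(path: str | Path) -> BeatSchedule:
    """Read a beat-time CSV (column ``beat_time_s``)."""
    df = pd.read_csv(path)
    return BeatSchedule(beat_times=df["beat_time_s"].to_numpy(dtype=float))
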