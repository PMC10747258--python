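"""Shared fixtures: synthetic recordings and (expensive) trained models.

Session scope keeps the costly pieces — the 5-minute corrupted corpus and
the VAE+SOM quality model trained on it — computed once for the whole run.
"""

from __future__ import annotations

import numpy as np
import pytest

import dopplerfhr as d


@pytest.fixture(scope="session")
def clean_constant():
    """60 s clean recording with a constant 0.4 s beat interval."""
    sched = d.make_beat_schedule(60.0, "constant", 0.4, seed=1)
    rec = d.synthesize_recording(sched, 1000.0, seed=1, duration=60.0)
    return sched, rec, d.preprocess(rec)


@pytest.fixture(scope="session")
def clean_sinusoidal():
    """60 s clean recording, interval swinging 0.35-0.45 s with 10 s period."""
    sched = d.make_beat_schedule(
        60.0, "sinusoidal", 0.4, {"amplitude": 0.05, "period": 10.0}, seed=1
    )
    rec = d.synthesize_recording(sched, 1000.0, seed=1, duration=60.0)
    return sched, rec, d.preprocess(rec)


@pytest.fixture(scope="session")
def corrupt_corpus():
    """5-minute recording with ~10% of its duration under strong artifacts.

    Returns the recording, integrated spectrum, usable interval estimates,
    SQA segments (as a matrix) and per-segment corruption labels.
    """
    sched = d.make_beat_schedule(
        300.0, "sinusoidal", 0.4, {"amplitude": 0.03, "period": 15.0}, seed=7
    )
    rec = d.synthesize_recording(sched, 1000.0, seed=7, duration=300.0)
    rec = d.corrupt_recording(
        rec,
        d.CorruptionSpec(
            fraction_corrupted=0.1, episode_len=1.2, noise_gain=5.0, rng_seed=8
        ),
    )
    integ = d.preprocess(rec)
    ests = [e for e in d.track(integ) if np.isfinite(e.frri_est)]
    starts = np.array([e.window_start for e in ests])
    segments = d.segment_for_sqa(integ, starts)
    X = np.stack([s.x for s in segments])
    labels = d.corruption_labels(rec, np.array([s.start for s in segments]))
    return {
        "recording": rec,
        "integrated": integ,
        "estimates": ests,
        "segments": segments,
        "X": X,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def trained_assessor(corrupt_corpus):
    """Quality model trained on the corrupted corpus (seed 0)."""
    return d.SignalQualityAssessor(vae_epochs=30, som_iterations=3000, seed=0).fit(
        corrupt_corpus["X"]
    )


@pytest.fixture()
def tiny_vae_config():
    """Small VAE configuration for fast unit tests."""
    return dict(latent_dim=3, channels=(2, 3), kernel=4, stride=2, input_len=16, seed=0)
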