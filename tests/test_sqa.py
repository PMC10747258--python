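"""Segmentation, combined-SQI mapping and the quality-assessor estimator."""

import numpy as np
import pytest

import dopplerfhr as d
from dopplerfhr.preprocessing import IntegratedSpectrum
from dopplerfhr.sqa import SEGMENT_LEN, SignalQualityAssessor, normalize_segments


def _series(values, step=1e-3):
    values = np.asarray(values, dtype=float)
    return IntegratedSpectrum(
        values=values, times=np.arange(values.size) * step, source_fs=1000.0
    )


class TestSegmentation:
    def test_constant_series_gives_constant_vectors(self):
        s = _series(np.full(5000, 3.5))
        segs = d.segment_for_sqa(s, [0.0, 1.0, 2.0])
        assert len(segs) == 3
        for seg in segs:
            assert seg.x.shape == (SEGMENT_LEN,)
            assert np.allclose(seg.x, 3.5)

    def test_resampling_preserves_endpoints(self):
        v = np.linspace(10.0, 20.0, 5000)
        segs = d.segment_for_sqa(_series(v), [1.0])
        seg = segs[0]
        assert seg.raw_len == 1200  # 1.2 s at 1 ms step
        raw = v[1000:2200]
        assert seg.x[0] == pytest.approx(raw[0])
        assert seg.x[-1] == pytest.approx(raw[-1])

    def test_tail_windows_skipped_with_warning(self):
        s = _series(np.random.default_rng(0).random(3000))
        with pytest.warns(UserWarning, match="skipped"):
            segs = d.segment_for_sqa(s, [0.0, 1.0, 2.5])
        assert [seg.start for seg in segs] == [0.0, 1.0]

    def test_most_tracker_windows_produce_segments(self, clean_constant):
        _, _, integ = clean_constant
        starts = [e.window_start for e in d.track(integ)]
        segs = d.segment_for_sqa(integ, starts)
        assert len(segs) >= len(starts) - 10  # only tail windows skipped


class TestCombinedSqi:
    def test_minmax_normalization(self):
        recs = d.combined_sqi(np.array([2.0, 4.0, 6.0]))
        assert [r.qe_norm for r in recs] == pytest.approx([0.0, 0.5, 1.0])

    def test_ramp_value_beyond_threshold(self):
        # th at the 0.6 quantile of 11 evenly spaced values is exactly 0.6
        recs = d.combined_sqi(np.linspace(0.0, 1.0, 11), th_quantile=0.6)
        by_norm = {round(r.qe_norm, 3): r.sqi for r in recs}
        assert by_norm[0.8] == pytest.approx(0.5)  # 1 - 0.2 / 0.4

    def test_endpoints(self):
        recs = d.combined_sqi(np.linspace(0.0, 1.0, 11), th_quantile=0.6)
        assert recs[-1].sqi == pytest.approx(0.0)  # qe_norm = 1
        assert all(r.sqi == 1.0 for r in recs if r.qe_norm <= 0.6)

    def test_degenerate_equal_qes_all_high_quality(self):
        recs = d.combined_sqi(np.full(10, 3.0))
        assert all(r.sqi == 1.0 for r in recs)

    def test_sqi_bounded_and_nonincreasing_in_qe(self):
        rng = np.random.default_rng(0)
        recs = d.combined_sqi(rng.lognormal(size=200))
        order = np.argsort([r.qe_norm for r in recs])
        sqis = np.array([r.sqi for r in recs])[order]
        assert np.all((sqis >= 0.0) & (sqis <= 1.0))
        assert np.all(np.diff(sqis) <= 1e-12)

    def test_at_least_90pct_full_quality_at_default_threshold(self):
        rng = np.random.default_rng(1)
        recs = d.combined_sqi(rng.lognormal(size=500))
        frac_ones = np.mean([r.sqi == 1.0 for r in recs])
        assert frac_ones >= 0.9


class TestNormalizeSegments:
    def test_rows_scaled_to_unit_interval(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 10.0, size=(20, 50))
        Xn = normalize_segments(X)
        assert np.allclose(Xn.min(axis=1), 0.0)
        assert np.allclose(Xn.max(axis=1), 1.0)

    def test_constant_row_maps_to_zero(self):
        Xn = normalize_segments(np.full((2, 10), 7.0))
        assert np.allclose(Xn, 0.0)


@pytest.fixture(scope="module")
def tiny_fitted():
    rng = np.random.default_rng(0)
    t = np.arange(SEGMENT_LEN)
    clean = 1.0 + np.sin(2 * np.pi * t / 400.0 + rng.uniform(0, 6.28, (60, 1)))
    noisy = rng.normal(1.0, 2.0, size=(6, SEGMENT_LEN))
    X = np.vstack([clean, noisy])
    ass = SignalQualityAssessor(
        latent_dim=4, vae_channels=(2, 4), vae_epochs=4, vae_batch_size=16,
        som_grid=(6, 6), som_iterations=500, seed=0,
    ).fit(X)
    return ass, X


class TestAssessor:

    def test_scores_bounded(self, tiny_fitted):
        ass, X = tiny_fitted
        sqi = ass.score_samples(X)
        assert np.all((sqi >= 0.0) & (sqi <= 1.0))

    def test_threshold_frozen_from_training_corpus(self, tiny_fitted):
        ass, X = tiny_fitted
        before = (ass.qe_min_, ass.qe_max_, ass.th_)
        ass.score_samples(X[:5])
        assert (ass.qe_min_, ass.qe_max_, ass.th_) == before

    def test_save_load_roundtrip(self, tiny_fitted, tmp_path):
        ass, X = tiny_fitted
        ass.save(tmp_path / "model")
        loaded = SignalQualityAssessor.load(tmp_path / "model")
        assert np.allclose(loaded.score_samples(X), ass.score_samples(X))
        assert loaded.th_ == ass.th_

    def test_unfitted_scoring_rejected(self):
        with pytest.raises(RuntimeError):
            SignalQualityAssessor().score_samples(np.zeros((2, SEGMENT_LEN)))


class TestAlignment:
    def test_exact_and_preceding_matches(self):
        seg_starts = np.array([0.0, 1.0, 2.0])
        sqi = np.array([0.1, 0.5, 0.9])
        got = d.sqa.align_sqi(np.array([0.0, 1.0, 2.7, 5.0]), seg_starts, sqi)
        assert got == pytest.approx([0.1, 0.5, 0.9, 0.9])
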