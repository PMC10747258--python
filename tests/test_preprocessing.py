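"""Pre-processing contracts: filtering, spectrogram, integration, despiking."""

import numpy as np
import pytest

import dopplerfhr as d
from dopplerfhr.preprocessing import IntegratedSpectrum
from dopplerfhr.recording import DusRecording


def _tone(freq, fs, dur=2.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return DusRecording(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)


def _fft_amplitude(x, fs, freq):
    spec = np.abs(np.fft.rfft(x)) * 2.0 / len(x)
    return spec[int(round(freq * len(x) / fs))]


class TestBandpass:
    def test_zero_input_zero_output(self):
        rec = DusRecording(samples=np.zeros(4000), fs=2000.0)
        assert np.allclose(d.bandpass(rec).samples, 0.0)

    def test_passband_tone_preserved_within_1pct(self):
        rec = _tone(100.0, 2000.0)
        out = d.bandpass(rec)
        ratio = _fft_amplitude(out.samples, 2000.0, 100.0) / _fft_amplitude(
            rec.samples, 2000.0, 100.0
        )
        assert abs(ratio - 1.0) < 0.01

    def test_stopband_tone_attenuated_20db(self):
        rec = _tone(5.0, 2000.0)
        out = d.bandpass(rec)
        ratio = _fft_amplitude(out.samples, 2000.0, 5.0) / _fft_amplitude(
            rec.samples, 2000.0, 5.0
        )
        assert ratio < 10 ** (-20 / 20)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        rec = _tone(100.0, 1000.0)
        with pytest.raises(ValueError):
            d.bandpass(rec, 25.0, 500.0)

    def test_output_length_matches_input(self):
        rec = _tone(100.0, 2000.0)
        assert len(d.bandpass(rec).samples) == len(rec.samples)


class TestStft:
    def test_zero_input_zero_power(self):
        rec = DusRecording(samples=np.zeros(2000), fs=1000.0)
        assert np.allclose(d.stft(rec).power, 0.0)

    def test_tone_peaks_in_correct_bin_vs_dft_oracle(self):
        fs = 1000.0
        rec = _tone(200.0, fs, dur=1.0)
        spec = d.stft(rec)
        interior = (spec.frame_times > 0.1) & (spec.frame_times < 0.9)
        argmax_freqs = spec.freqs[np.argmax(spec.power[interior], axis=1)]
        bin_width = spec.freqs[1] - spec.freqs[0]
        assert np.all(np.abs(argmax_freqs - 200.0) <= bin_width)
        # brute-force DFT of one interior frame agrees with the power row
        i = int(np.flatnonzero(interior)[10])
        t0 = spec.frame_times[i]
        c0 = int(round(t0 * fs))
        half = int(round(spec.window_len * fs)) // 2
        seg = rec.samples[c0 - half : c0 + half] * np.hanning(2 * half)
        n = len(seg)
        k = np.arange(n // 2 + 1)
        dft = np.array([np.abs(np.sum(seg * np.exp(-2j * np.pi * kk * np.arange(n) / n))) for kk in k])
        assert k[np.argmax(dft**2)] == np.argmax(spec.power[i])

    def test_frame_count_matches_duration_over_step(self):
        rec = _tone(100.0, 1000.0, dur=5.0)
        spec = d.stft(rec)
        assert abs(len(spec.frame_times) - 5000) <= 64

    def test_too_short_recording_rejected(self):
        rec = DusRecording(samples=np.zeros(32), fs=1000.0)
        with pytest.raises(ValueError):
            d.stft(rec)


class TestIntegrateSpectrum:
    def test_zero_spectrogram_zero_series(self):
        rec = DusRecording(samples=np.zeros(2000), fs=1000.0)
        integ = d.integrate_spectrum(d.stft(rec))
        assert np.allclose(integ.values, 0.0)

    def test_steady_tone_interior_nearly_constant(self):
        integ = d.integrate_spectrum(d.stft(_tone(200.0, 1000.0)))
        interior = integ.values[200:-200]
        assert np.std(interior) / np.mean(interior) < 0.05

    def test_amplitude_doubling_quadruples_power(self):
        a = d.integrate_spectrum(d.stft(_tone(200.0, 1000.0, amp=1.0)))
        b = d.integrate_spectrum(d.stft(_tone(200.0, 1000.0, amp=2.0)))
        interior = slice(200, -200)
        assert np.allclose(b.values[interior], 4.0 * a.values[interior], rtol=1e-8)

    def test_empty_band_rejected(self):
        spec = d.stft(_tone(200.0, 1000.0))
        with pytest.raises(ValueError):
            d.integrate_spectrum(spec, 501.0, 510.0)

    def test_nonnegative_and_length_preserving(self, clean_constant):
        _, rec, _ = clean_constant
        spec = d.stft(rec)
        integ = d.integrate_spectrum(spec)
        assert np.all(integ.values >= 0)
        assert len(integ.values) == spec.power.shape[0]


class TestRemoveSpikes:
    def _smooth(self):
        t = np.linspace(0, 10, 2001)
        return IntegratedSpectrum(
            values=2.0 + np.sin(2 * np.pi * t / 3.0) ** 2, times=t, source_fs=1000.0
        )

    def test_smooth_series_unchanged(self):
        s = self._smooth()
        assert np.array_equal(d.remove_spikes(s).values, s.values)

    def test_single_spike_replaced_near_local_level(self):
        s = self._smooth()
        spiked = IntegratedSpectrum(values=s.values.copy(), times=s.times, source_fs=s.source_fs)
        spiked.values[1000] *= 100.0
        out = d.remove_spikes(spiked)
        assert abs(out.values[1000] - s.values[1000]) / s.values[1000] < 0.01
        untouched = np.ones_like(s.values, dtype=bool)
        untouched[1000] = False
        assert np.array_equal(out.values[untouched], s.values[untouched])

    def test_constant_with_spike_restored_exactly(self):
        v = np.full(501, 3.0)
        v[250] = 300.0
        s = IntegratedSpectrum(values=v, times=np.arange(501) * 1e-3, source_fs=1000.0)
        assert np.array_equal(d.remove_spikes(s).values, np.full(501, 3.0))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            d.remove_spikes(self._smooth(), win=10)


def test_preprocess_is_deterministic(clean_constant):
    _, rec, integ = clean_constant
    again = d.preprocess(rec)
    assert np.array_equal(again.values, integ.values)
    assert np.array_equal(again.times, integ.times)


def test_integrated_spectrum_peaks_align_with_beats(clean_constant):
    """Local maxima of the envelope sit within a burst width of true beats."""
    sched, _, integ = clean_constant
    for tb in sched.beat_times[5:15]:
        seg = integ.segment(tb - 0.1, tb + 0.1)
        t_peak = tb - 0.1 + np.argmax(seg) * integ.step
        assert abs(t_peak - tb) <= 0.02
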