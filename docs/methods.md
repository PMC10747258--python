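# Methods

`dopplerfhr` estimates beat-to-beat fetal heart rate (FHR) from a
single-channel Doppler-ultrasound (DUS) recording and scores, without any
quality labels, how trustworthy each estimate is.  This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Signal model and pre-processing

Fetal cardiac wall/valve motion modulates the DUS signal quasi-periodically;
its energy lives roughly in 25–500 Hz, while content below 25 Hz is dominated
by movement and equipment noise.  Pre-processing converts the raw signal
`x(t)` (sampled at `fs ≥ 1` kHz) into a periodicity-enhancing envelope:

1. **Band-limiting.** 4th-order Butterworth, 25–500 Hz, applied
   forward–backward (`sosfiltfilt`) so no group delay shifts event timing.
   At `fs = 1` kHz the upper edge coincides with Nyquist, where a band-pass
   is undefined; the pipeline then degrades to a 25 Hz high-pass (the upper
   cutoff is vacuous below Nyquist) and relies on the spectrogram-band
   integral for the upper edge.
2. **Spectrogram.** STFT with a 64 ms Hann window and 1 ms step; power
   (magnitude-squared) spectra; frame times at window centers; edge frames
   on zero-padded windows.  Power rather than magnitude makes the
   amplitude-squared scaling of the envelope exact and testable.
3. **Band integration.** Per-frame sum of power over bins in [25, 500] Hz
   (inclusive), yielding the *integrated spectrum*: one value per
   millisecond.
4. **Despiking.** A rolling median/MAD detector (window 51 frames, k = 5)
   replaces samples above `median + k·MAD` by the rolling median.  The MAD
   is floored at 1% of the local median: on locally flat stretches the raw
   MAD collapses toward zero and would otherwise flag smooth samples.  The
   detector is deliberately parameter-light; it removes isolated impulses
   without touching the beat periodicity.

## Double-autocorrelation interval estimation

For a window of the integrated spectrum the normalized autocorrelation is

    acf_k = Σ_{i=1}^{N−k} (Y_i − Ȳ)(Y_{i+k} − Ȳ) / Σ_{i=1}^{N} (Y_i − Ȳ)²,

whose highest peak at physiological lags marks the beat interval (FRRI).
Each analysis position `t0` runs two passes:

* **Pass 1** on `[t0, t0 + S]` with `S = 3.75` s (the window standard in
  computerized fetal non-stress-test analysis).  The highest strict local
  maximum with lag in `[FRRI_min, FRRI_max] = [0.25, 1.2]` s (240 down to
  50 bpm) gives the approximate interval `FRRI_app`.  A harmonic check
  replaces the peak by a sub-multiple: if a local maximum exists within
  `peak/2 ± range/2` whose ACF value is ≥ α = 0.75 of the peak's, it wins,
  recursively until stable.  Ties break toward smaller lag, favoring the
  fundamental.
* **Pass 2** on the resized window `[t0, t0 + S_new]`,
  `S_new = 2·FRRI_app + Δ` with `Δ = FRRI_app/2` (just over two cardiac
  cycles), searching only `FRRI_app ± range` with `range = 0.1` s.  The
  peak is the refined estimate `FRRI_est`.

The window then advances by `FRRI_est / 2` (about two estimates per beat)
and pass 1 restarts at length `S`.  Failed windows (no usable peak) are
flagged, carried as `FRRI_app` where possible, and the tracker still
advances (`FRRI_app/2`, else `S/2`) so timestamps stay monotone.

Numerical choices: lag resolution equals the envelope step (1 ms, well
below the target error; no sub-sample interpolation); the pass-2 window is
left-anchored at `t0` (it replaces the pass-1 window in place); a constant
(zero-variance) window raises a degenerate-input condition handled as "no
peak".  `FRRI_min/FRRI_max`, `range`, α and Δ are all configuration fields.

## Unsupervised signal-quality assessment

The quality model assumes most segments of a recording are clean, so
low-quality segments are outliers in representation space.

**Segments.** 1.2 s windows of the integrated spectrum (the average resized
pass-2 window), aligned to the tracker's window starts and linearly
resampled to 1024 samples.  Each segment is min–max normalized to [0, 1]
before encoding; bounded inputs stabilize the reconstruction loss across
amplitude scales.

**VAE.** A fully convolutional variational autoencoder: five encoder blocks
(1-D convolution, kernel 16, stride 2 → batch normalization → ELU) with
channel plan (8, 16, 24, 32, 40) compress 1024 samples to a 40 × 32 map;
two dense heads emit the mean `μ_z` and log-variance of a 32-dimensional
Gaussian latent code; the decoder mirrors the encoder with transposed
convolutions (final layer linear).  The loss per segment is

    L = (1/L) Σ_l (x_l − x̂_l)² + ½ Σ_i (μ_i² + σ_i² − log σ_i² − 1),

i.e. mean squared reconstruction error plus the KL divergence of
`N(μ, σ²)` from `N(0, I)`, minimized by Adam (lr 10⁻³) over mini-batches of
64 for 100 epochs (default).  The log-variance is clipped to ±15 for
numerical safety, with gradients gated in the clipped region.  All layers
are implemented in NumPy with explicit backpropagation; the analytic
gradients are verified against finite differences in the test suite.

**SOM.** The latent means are quantized by a 30 × 30 self-organizing map
trained by random-sample competitive learning for 15,000 iterations
(default): learning rate 0.5 and Gaussian neighborhood width (initially
half the grid) both decaying as `1/(1 + t/(T/2))`; prototypes initialized
from random training vectors.  The quantization error (QE) of a vector is
the Euclidean distance to its best-matching prototype.

**Combined SQI.** Training QEs are min–max normalized; the threshold `th`
is their 90th percentile, encoding the expectation that roughly 90% of
segments are clean; and

    SQI = 1                          if qe_norm ≤ th
          1 − (qe_norm − th)/(1 − th) otherwise,

a ramp from 1 down to 0 at `qe_norm = 1`.  The stated "9th decile of all
SQI values" definition is circular as printed (SQI is defined from `th`);
this package resolves it as the 9th decile of normalized QEs, which fixes
the stated intent.  QE normalization constants and `th` are frozen at fit
time, so scoring never depends on the batch being scored; out-of-range QEs
on new data are clipped into [0, 1].  Degenerate case: if all training QEs
are equal, every segment scores 1.

## SQI-adaptive Kalman refinement

The interval series is modeled as a random walk observed in noise (unit
state transition).  Two scalar Kalman filters run in cascade:

1. fixed-noise smoothing with `R0 = 1`, `Q0 = 0.1`;
2. an adaptive filter (`R0 = 1`, `Q0 = 1`) whose per-step measurement
   noise is `R_m = R0 · exp(1/SQI_m² − 1)` — equal to `R0` at SQI 1 and
   astronomically large as SQI → 0, driving the gain to zero so the
   measurement is ignored.

The narrative order ("first … to smooth", then "applied to refine")
motivates the cascade; a configuration flag (`cascade=False`) runs the
adaptive filter from the raw series instead.  The SQI is floored at 10⁻³
and the exponent capped at 700, realizing the intended K → 0 limit without
floating-point overflow.  The filter state starts at the first measurement
with `P0 = 1`, avoiding transient bias.

Estimates from **runs of ≥ 4 consecutive low-quality segments** ("more than
three consecutive") are discarded outright; "low" means SQI strictly below
the 8th decile of the recording's SQIs (per-recording, not per-corpus).
Short low runs are retained — the adaptive filter can still correct them.

## Evaluation

`FHR = 60 / FRRI` (bpm, FRRI in seconds).  Metrics over estimates paired to
ground truth: RMSE of the interval (ms), averaged absolute FHR error AAE
(bpm), and coverage — retained estimates as a percentage of all emitted
estimates.  The pairing rule is this package's own construction (the source
method's rule is unstated): each estimate's reference time is
`window_start + S_new/2`, matched to the inter-beat gap containing it
(`nearest-midpoint` is available as an alternative); references outside the
annotated span are dropped.  Estimates with no usable value (both passes
failed) emit nothing and are excluded from numerator and denominator alike.
The normalized absolute error `NAE = |est − true| / true` with threshold
0.03 serves as a proxy quality label.

The scenario harness compares, on shared rough estimates: raw estimation
only; hard removal of estimates with SQI below the 8th decile; fixed-noise
Kalman smoothing; and the full adaptive refinement.

## Synthetic benchmark

No public annotated DUS corpus exists, so the simulator generates the
statistical structure the pipeline assumes:

* **Beat schedules** — constant, sinusoidal or piecewise interval patterns
  with optional Gaussian jitter, constrained to [0.25, 1.2] s.
* **Bursts** — per beat, two Gaussian-windowed tone bursts ≈ 50 ms wide
  (valve open/close pair; the second at 0.35 of the nominal interval, 0.6
  amplitude), carriers drawn uniformly in [100, 300] Hz; Gaussian noise
  floor at 10 dB SNR.  This yields one dominant ACF peak per cardiac cycle,
  the property the estimator relies on.
* **Corruption** — broadband noise episodes of 1.2 s at 5× the clean RMS,
  covering a configurable fraction (default 10%) of the duration on a
  non-overlapping grid; beat-time ground truth is preserved and a
  per-sample mask records affected spans.

Benchmark conditions: 60 s recordings at 1 kHz for the interval-recovery
checks; the quality-model benchmark uses a 5-minute recording (≈ 1300
segments, enough to train the quality model the way a clinical corpus of a
few thousand segments would) with 10% corruption, VAE trained 30 epochs and
SOM 3,000 iterations — reduced from the 100-epoch / 15,000-iteration
package defaults.

What the simulator does **not** emulate: maternal-heart interference,
transducer repositioning, slow SNR drift, tissue-propagation acoustics, and
real burst morphology (published descriptions of DUS envelopes are only
qualitative, so the simulator is calibrated to the one property the
estimator depends on — an ACF peak at the true period).
Passing tests therefore establish internal correctness and the claimed
qualitative behavior (quality discrimination, refinement benefit), not
clinical-grade accuracy on real recordings.

## Known limitations

* The exact spike-removal algorithm, harmonic-rejection rule and
  `FRRI_min/max` of the source method's references are not public; the
  stand-ins above implement their stated intent with exposed tunables.
* SQI is computed from a 1.2 s segment at the window start, while the
  pass-1 window spans 3.75 s; a window can be degraded by an artifact its
  SQI segment does not cover.
* Single-channel, offline operation only; no maternal-rate rejection; the
  VAE/SOM must be retrained for other sampling rates or envelope scales.
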