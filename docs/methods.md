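# Methods

## Signal model

A head-tremor recording is modelled as triaxial angular velocity

    omega(t) = s(t) * u + d(t) + e(t)

where `u` is a fixed unit rotation axis, `s(t)` the 1-D tremor, `d(t)` slow
postural drift and `e(t)` white sensor noise. The tremor is built cycle by
cycle: cycle *i* has frequency `f_i ~ Normal(f0, sigma_f)` truncated to the
physiological band 2–12 Hz and duration `1/f_i`, with phase continuous across
boundaries; its amplitude is `A_i = A0 * exp(e_i)` with `e_i` a stationary
AR(1) Gaussian process (coefficient `rho_A`, SD `sigma_logA`), giving the
slow waxing and waning seen in real tremor. Drift is the sum of two sinusoids
with frequencies drawn below 0.15 Hz (under the 0.2 Hz detrend cutoff, so the
chain can remove it); noise is i.i.d. Gaussian per axis. Everything is
deterministic given the seed.

Generator parameters, units and defaults:

| parameter    | meaning                                   | default  |
|--------------|-------------------------------------------|----------|
| `f0`         | mean tremor frequency (Hz)                | 5.0      |
| `sigma_f`    | per-cycle frequency jitter SD (Hz)        | 0.0      |
| `A0`         | median cycle amplitude (deg/s)            | 4.0      |
| `sigma_logA` | log-amplitude SD                          | 0.0      |
| `rho_A`      | AR(1) amplitude correlation               | 0.0      |
| `drift_amp`  | total drift amplitude (deg/s)             | 0.0      |
| `noise_sd`   | sensor noise SD per axis (deg/s)          | 0.0      |
| `duration`   | recording length (s)                      | 10       |
| `rate`       | sampling rate (Hz)                        | 66.67    |

Amplitude is specified directly in angular-velocity units because all
features operate on gyroscope output; no displacement/differentiation
convention is needed. Optional quantization at the gyroscope's finest
resolution (0.00763 deg/s) is off by default — it is negligible at tremor
amplitudes.

## Processing chain

Trim 10% per end → zero-phase order-3 Butterworth high-pass at 0.2 Hz →
PCA projection onto the leading covariance eigenvector (sign fixed so the
largest-magnitude loading is positive) → autocorrelation dominant frequency
→ zero-phase band-pass f_ac ± 2 Hz → cycle and spectral features.

**Autocorrelation f_ac.** Biased-estimator autocorrelation normalized to
r(0)=1, computed by FFT but exactly equal to the plain lag sum. Candidate
lags span one period of the band edges (2–12 Hz); the *highest* local maximum
wins (an alternative "first local maximum" rule is a configuration option),
ties toward the smaller lag. If no in-band local maximum exists (aperiodic
motion), the estimate falls back to the spectral peak and is flagged.

**Filtering.** All filters are Butterworth, applied forward-backward
(zero net phase, squared magnitude response). Two numerical choices matter:

- *Padding.* Forward-backward filtering needs edge extension. The scipy
  default odd (anti-symmetric) extension fails badly here: a 0.2 Hz
  high-pass has poles that ring for seconds, and the odd extension of an
  oscillation that ends mid-cycle injects a step-like low-frequency kink,
  producing edge errors comparable to the signal amplitude. Even (mirror)
  extension keeps the extension kink-free; residual edge transients decay
  within ~1–2 s and are the reason cycle statistics use the whole trimmed
  trace but tight tone tolerances are verified mid-signal.
- *Orders.* The detrend high-pass is order 3. The band-pass halves are
  order 8 each: because forward-backward application squares the magnitude
  response, an order-4 half would attenuate a center-frequency tone by ~8%
  (low-pass half alone: 1/(1+(5/7)^8) ≈ 0.937), biasing every amplitude
  feature; order 8 keeps the cascade within ~1% of unity at the center while
  attenuating a tone 4 Hz away by >15 dB. When the high-pass edge clamps to
  its 0.2 Hz floor (f_ac ≤ 2.2 Hz), that half's order is capped at 4 — an
  order-8 section at 0.003 of the sampling rate is numerically marginal.
  Orders are configurable.

**Peak detection.** Strict local extrema, minimum prominence 0.1× the
trace's interdecile range (rejects harmonic ripple without an absolute
threshold), minimum same-type separation `0.5/(f_ac+2)` s, alternation
enforced by keeping the larger-magnitude extremum of any same-type run.
Peak times and values are then refined by a 3-point parabolic fit: at
66.67 Hz the raw sample grid aliases a pure 5 Hz tone's period into a
13/14-sample alternation, which alone would inflate regularity_std to
~0.007 s and ICVF spread to ~0.5 Hz; the refinement removes this artifact
(regularity_std ~0.002 s on a pure tone). The brute-force test oracle
compares the integer extremum indices, which the refinement does not touch.

**Spectrum and SPCR.** Hann-windowed periodogram zero-padded to ≥8× the
trace length (power-of-two FFT), normalized so the trapezoid integral over
[0, rate/2] equals the windowed signal's mean square. `fc` is the in-band
argmax; SPCR integrates S over fc ± 0.5 Hz and fc ± 2 Hz by trapezoid with
interpolated band edges. SPCR is reported as a fraction in (0, 1]; percent
renderings multiply by 100. Note that for featureless noise the *expected*
SPCR exceeds the bandwidth ratio 0.25 because fc is itself the argmax of the
noisy spectrum (selection bias); the flat-spectrum limit is recovered when
the center frequency is fixed a priori.

**Summaries.** Mean, sample SD (n−1), and IQR with linear-interpolation
quartiles, over the interleaved amplitude series (A⁻, A⁺), the maxima-to-
maxima period series, and the ICVF increments. ICVF frequencies use
maxima-to-maxima periods only.

## Cohort statistics

Group comparison: per-feature Welch t-test (default) or Mann–Whitney,
two-sided, raw p-values — no multiplicity correction across the 11 features,
deliberately, matching common reporting practice for this analysis; treat
borderline p-values accordingly. ROC: thresholds at midpoints of consecutive
unique scores bracketed by ±∞, `score ≥ threshold` predicts positive,
trapezoid AUC (provably the tie-adjusted probability that a random positive
outscores a random negative). Operating point: maximize Youden's
J = sensitivity + specificity − 1, ties toward the lower threshold; a
degenerate curve returns the −∞ endpoint with a warning. AUC confidence
interval: stratified percentile bootstrap (2000 resamples, seeded). The
convenience `discriminate()` makes the second group the positive class and
flips the score sign (reported) when AUC < 0.5, so curves read
conventionally; SPCR, for instance, is *higher* in essential tremor.

## Cohort presets and calibration

Four presets emulate the published group structure: `A1-like` (cervical
dystonia without head tremor, n=75), `B1-like`/`B2-like` (CD with head
tremor, n=96), `A2-like` (essential head tremor, n=78).

- Frequency: `f0` per patient from truncated normals with the printed group
  moments (4.92±1.62, 4.37±1.22, 4.25±0.883 Hz).
- Amplitude: `A0` log-normal, matched in closed form to half the printed
  amplitude-mean moments (peak-to-trough ≈ 2·A0). Log-normal because the
  printed SDs rival or exceed the means, ruling out symmetric positive
  distributions.
- Jitter: `sigma_f` log-normal (CV 0.3) with group means 2.2 / 1.45 / 0.9 Hz
  for A1 / B1,B2 / A2, calibrated through the pipeline's SPCR response to
  land near the printed fractional SPCR means (0.46 / 0.52 / 0.63). A1 — a
  group without clinically observable tremor — is approximated as
  low-amplitude, high-jitter oscillation plus drift; that is a modelling
  choice, not an established model of non-tremor dystonic motion.
- Within-recording amplitude modulation `sigma_logA = 0.55`, `rho_A = 0.9`
  (matches the printed within-recording amplitude CVs of ~0.6–0.7);
  drift 0.2–1.0 deg/s; noise 0.25 deg/s per axis.

What the generator does *not* capture: jerky non-sinusoidal dystonic
movements, harmonics, voluntary motion artifacts, amplitude-frequency
coupling, and recording-quality failures. One measurable consequence: the
pipeline's ICVF spread saturates near ~1.1 Hz on these quasi-sinusoidal
signals (the ±2 Hz band-pass bounds the cycle-to-cycle excursions a peak
detector can see), below the 1.6–2.7 Hz printed for clinical recordings,
whose excess irregularity presumably comes from exactly the unmodelled
non-sinusoidal components. The group *ordering* of ICVF spread and SPCR is
preserved, which is what the discrimination checks rely on. Passing tests
therefore demonstrate correctness of the chain and qualitative
reproducibility of the group findings, not clinical-scale feature
magnitudes.

## Problem sizes and determinism

The verification suite uses: 10 s recordings at 66.67 Hz (667 samples);
a 6-point `sigma_f` grid × 50 seeds for monotonicity (Spearman rho on
per-grid means); 100 cohort replicates at full preset sizes for the
discrimination fractions (50 in the acceptance script); 200 replicates of
two 12-patient null cohorts for type-I calibration (Mann–Whitney, whose
level is exact under exchangeability regardless of the feature's skewed
distribution). The peak-frequency null check uses an A2 variant sharing
B2's `f0` distribution, isolating the frequency feature from the small
printed group difference. All randomness flows from explicit seeds; repeat
runs are bit-identical.
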