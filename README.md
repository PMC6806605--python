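# tremorkit

Quantification of head tremor from wearable triaxial gyroscope recordings,
for researchers and clinicians studying movement disorders — in particular
the differential assessment of essential tremor (ET) versus cervical dystonia
(CD) with head tremor. Head tremor is rotational motion, so a head-mounted
gyroscope (angular velocity, deg/s, free of gravitational artifacts) is the
natural sensor; a typical bedside recording is ~10 s at ~66.67 Hz.

Because no public head-tremor dataset of this kind exists, the package ships
a synthetic tremor-recording generator with known per-cycle ground truth, so
every stage of the analysis is testable end to end.

## The processing chain and features

Each recording (CSV columns `timestamp,x,y,z`) is reduced to a scalar
feature vector:

1. **Trim** the first and last 10% of samples (settling motion).
2. **Detrend** with a zero-phase Butterworth high-pass at 0.2 Hz.
3. **PCA**: project the triaxial signal onto its dominant rotation axis;
   the first principal component is the 1-D tremor trace.
4. **f_ac**: dominant frequency from the autocorrelation's principal
   non-zero-lag peak (searched in 2–12 Hz).
5. **Band-pass** f_ac ± 2 Hz (zero-phase high/low-pass pair).
6. **Features** from the band-passed trace s(t):
   - peak frequency `fc`: argmax of the Hann-windowed power spectrum S(f);
   - amplitude: peak-to-trough differences of alternating extrema,
     `Aᵢ⁻ = |pᵢ⁺ − pᵢ⁻|`, `Aᵢ⁺ = |pᵢ₊₁⁻ − pᵢ⁺|` (mean, std, IQR);
   - regularity: inter-maximum periods `ΔTᵢ = tᵢ₊₁⁺ − tᵢ⁺` (mean, std, IQR);
   - ICVF (inter-cycle variation of frequency): `Δfᵢ = fᵢ₊₁ − fᵢ` with
     `fᵢ = 1/ΔTᵢ` (mean, std, IQR) — its spread quantifies irregularity;
   - SPCR (signal power concentration ratio):
     `PR = ∫_{fc−0.5}^{fc+0.5} S df ÷ ∫_{fc−2}^{fc+2} S df`, near 1 for a
     spectrally pure (regular) tremor.

Cohort analysis: per-feature group means ± SD with Welch or Mann–Whitney
p-values, and single-feature ROC curves with trapezoid AUC (exactly the
tie-adjusted pairwise-comparison probability), stratified-bootstrap 95% CI,
and the Youden-optimal operating threshold.

## Worked example

```bash
python examples/02_cohort_discrimination.py
```

simulates a 75-patient cohort shaped like CD without head tremor (A1-like)
against a 96-patient cohort with head tremor (B1-like), extracts all
features, and prints the comparison table and the amplitude ROC:

```
                   mean_a    sd_a     mean_b    sd_b   p_value
feature
peak_frequency      3.911   1.425       4.22   1.212    0.1349
amplitude_mean      1.383   1.698      7.276   5.794 4.655e-16
...
icvf_std            1.115  0.2344     0.8962  0.2001 1.614e-09
spcr               0.4774  0.1152     0.5358  0.1121  0.001083

amplitude_mean AUC = 0.913 (95% bootstrap CI 0.865-0.954)
optimal threshold  = 1.491 deg/s (sensitivity 0.938, specificity 0.787)
```

Reading: the tremor group has far larger cycle amplitudes (p ≈ 5e-16) and
*more* regular cycles (lower ICVF spread, higher SPCR), while peak frequency
does not discriminate — a recording whose mean cycle amplitude exceeds the
printed threshold is flagged as tremor-positive. `examples/01_single_recording.py`
walks one recording, `examples/03_recording_io_and_stages.py` the individual
stages.

A thin CLI mirrors the workflow: `tremorkit simulate | features | cohort | roc`
(see `tremorkit --help`).

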