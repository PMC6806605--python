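"""Temporal and spectral tremor features from a band-passed 1-D trace.

Cycle-level quantities come from alternating extrema of the trace:

* amplitude — absolute peak-to-trough differences ``A_i- = |p_i+ - p_i-|``,
  ``A_i+ = |p_(i+1)- - p_i+|`` (deg/s), interleaved into one series;
* regularity — inter-maximum intervals ``dT_i = t_(i+1)+ - t_i+`` (s);
* ICVF — inter-cycle variation of frequency ``df_i = f_(i+1) - f_i`` with
  ``f_i = 1/dT_i`` (Hz); its spread quantifies tremor irregularity.

Spectral quantities come from a Hann-windowed, zero-padded periodogram:
the peak frequency fc in the physiological band and SPCR, the ratio of power
within +/-0.5 Hz of fc to power within +/-2 Hz — near 1 for a regular tremor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .io import GyroRecording, FEATURE_COLUMNS
from .preprocess import (
    DEFAULT_BAND,
    AutocorrEstimate,
    PreprocessError,
    TremorTrace,
    autocorr_dominant_freq,
    bandpass_around,
    highpass_detrend,
    principal_axis,
    trim_segments,
)


class FeatureError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PeakSeries:
    """Alternating local maxima (p+, t+) and minima (p-, t-) of a trace.

    Times are sub-sample (parabolic-refined); ``idx_plus``/``idx_minus`` keep
    the raw sample indices the refinement started from.
    """

    t_plus: np.ndarray
    p_plus: np.ndarray
    t_minus: np.ndarray
    p_minus: np.ndarray
    idx_plus: np.ndarray
    idx_minus: np.ndarray

    def merged(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Times, values, and type flags (+1 max / -1 min) in time order."""
        t = np.concatenate([self.t_plus, self.t_minus])
        p = np.concatenate([self.p_plus, self.p_minus])
        kind = np.concatenate(
            [np.ones(len(self.t_plus)), -np.ones(len(self.t_minus))]
        )
        order = np.argsort(t)
        return t[order], p[order], kind[order]

    def validate(self) -> None:
        t, _, kind = self.merged()
        if np.any(kind[1:] == kind[:-1]):
            raise FeatureError("extrema do not alternate")
        if np.any(np.diff(t) <= 0):
            raise FeatureError("extrema times not strictly increasing")


@dataclass
class CycleSeries:
    """Per-cycle amplitudes, periods, frequencies and frequency increments."""

    A: np.ndarray  # deg/s, interleaved A_i-, A_i+
    dT: np.ndarray  # s, maxima-to-maxima periods
    f: np.ndarray  # Hz, 1/dT
    df: np.ndarray  # Hz, successive differences of f


@dataclass
class SpectrumEstimate:
    """One-sided power spectral density and its in-band peak frequency."""

    f: np.ndarray  # Hz
    S: np.ndarray  # (deg/s)^2 / Hz
    fc: float  # Hz


@dataclass
class FeatureSet:
    """The scalar feature vector for one recording, plus diagnostics."""

    peak_frequency: float
    amplitude_mean: float
    amplitude_std: float
    amplitude_iqr: float
    regularity_mean: float
    regularity_std: float
    regularity_iqr: float
    icvf_mean: float
    icvf_std: float
    icvf_iqr: float
    spcr: float
    f_ac: float
    pc1_evr: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}


# Peak detection -----------------------------------------------------------


def _parabolic_refine(x: np.ndarray, idx: np.ndarray, rate: float):
    """Sub-sample peak location/value by a quadratic fit through 3 points.

    Sample-grid quantization alone would alias a pure tone's period into a
    two-value sequence (e.g. 13 vs 14 samples at 66.67 Hz for 5 Hz), inflating
    the regularity and ICVF spreads; the parabolic fit removes that artifact.
    """
    y0 = x[idx - 1]
    y1 = x[idx]
    y2 = x[idx + 1]
    denom = y0 - 2 * y1 + y2
    delta = np.where(denom != 0, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    t = (idx + delta) / rate
    value = y1 - 0.25 * (y0 - y2) * delta
    return t, value


def _strict_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (both neighbors smaller/larger)."""
    interior = np.arange(1, len(x) - 1)
    maxima = interior[(x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])]
    minima = interior[(x[interior] < x[interior - 1]) & (x[interior] < x[interior + 1])]
    return maxima, minima


def _greedy_min_separation(
    idx: np.ndarray, magnitude: np.ndarray, min_sep: int
) -> np.ndarray:
    """Keep extrema in decreasing magnitude order, rejecting any closer than
    ``min_sep`` samples to an already-kept one.  Ties go to the earlier index."""
    order = np.lexsort((idx, -magnitude))
    kept: list[int] = []
    for j in order:
        i = idx[j]
        if all(abs(i - k) >= min_sep for k in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def detect_peaks(
    trace: TremorTrace,
    f_ac: float,
    min_prominence_frac: float = 0.1,
) -> PeakSeries:
    """Alternating extrema of a band-passed trace.

    Rules: strict local extrema, minimum prominence ``min_prominence_frac``
    times the interdecile range of the trace, minimum same-type separation
    ``0.5 / (f_ac + 2)`` seconds, and alternation enforced by keeping the
    larger-magnitude extremum of any same-type run.
    """
    x = trace.samples
    max_idx, min_idx = _strict_extrema(x)
    if len(max_idx) == 0 or len(min_idx) == 0:
        raise FeatureError("insufficient cycles: no local extrema found")
    p10, p90 = np.percentile(x, [10, 90])
    prom_thresh = min_prominence_frac * (p90 - p10)
    if len(max_idx):
        prom_max = sps.peak_prominences(x, max_idx)[0]
        max_idx = max_idx[prom_max >= prom_thresh]
    if len(min_idx):
        prom_min = sps.peak_prominences(-x, min_idx)[0]
        min_idx = min_idx[prom_min >= prom_thresh]
    min_sep = max(1, int(round(0.5 / (f_ac + 2.0) * trace.rate)))
    max_idx = _greedy_min_separation(max_idx, x[max_idx], min_sep)
    min_idx = _greedy_min_separation(min_idx, -x[min_idx], min_sep)

    # merge and collapse runs of the same type, keeping the larger magnitude
    merged = sorted(
        [(i, +1) for i in max_idx] + [(i, -1) for i in min_idx]
    )
    collapsed: list[tuple[int, int]] = []
    for i, kind in merged:
        if collapsed and collapsed[-1][1] == kind:
            prev_i = collapsed[-1][0]
            better = (kind * x[i]) > (kind * x[prev_i])  # strict: ties keep earlier
            if better:
                collapsed[-1] = (i, kind)
        else:
            collapsed.append((i, kind))
    if len(collapsed) < 3:
        raise FeatureError(
            f"insufficient cycles: only {len(collapsed)} alternating extrema"
        )
    plus = np.array([i for i, k in collapsed if k == +1], dtype=int)
    minus = np.array([i for i, k in collapsed if k == -1], dtype=int)
    t_plus, p_plus = _parabolic_refine(x, plus, trace.rate)
    t_minus, p_minus = _parabolic_refine(x, minus, trace.rate)
    return PeakSeries(
        t_plus=t_plus,
        p_plus=p_plus,
        t_minus=t_minus,
        p_minus=p_minus,
        idx_plus=plus,
        idx_minus=minus,
    )


# Cycle-level series -------------------------------------------------------


def amplitude_series(peaks: PeakSeries) -> np.ndarray:
    """Interleaved peak-to-trough amplitudes |p_i+ - p_i-| of consecutive extrema."""
    _, p, _ = peaks.merged()
    return np.abs(np.diff(p))


def regularity_series(peaks: PeakSeries) -> np.ndarray:
    """Inter-maximum intervals dT_i = t_(i+1)+ - t_i+ in seconds."""
    if len(peaks.t_plus) < 2:
        raise FeatureError("need at least 2 maxima for regularity")
    return np.diff(peaks.t_plus)


def icvf_series(dT: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle frequencies f_i = 1/dT_i and their increments df_i."""
    dT = np.asarray(dT, dtype=float)
    if np.any(dT <= 0):
        raise FeatureError("non-positive cycle period")
    f = 1.0 / dT
    return f, np.diff(f)


def cycle_series(peaks: PeakSeries) -> CycleSeries:
    """Bundle amplitude/period/frequency series derived from one PeakSeries."""
    dT = regularity_series(peaks)
    f, df = icvf_series(dT)
    return CycleSeries(A=amplitude_series(peaks), dT=dT, f=f, df=df)


# Spectrum -----------------------------------------------------------------


def estimate_spectrum(
    trace: TremorTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    pad_factor: int = 8,
) -> SpectrumEstimate:
    """Hann-windowed, zero-padded periodogram with an in-band peak frequency.

    The density is normalized so the trapezoid integral over [0, rate/2]
    equals the mean square of the windowed signal; zero-padding to at least
    ``pad_factor`` times the length (rounded up to a power of two) gives a
    frequency grid fine enough for SPCR band integrals.
    """
    x = np.asarray(trace.samples, dtype=float)
    n = len(x)
    if n < 64:
        raise FeatureError("need at least 64 samples for a spectrum")
    w = sps.windows.hann(n, sym=False)
    xw = x * w
    nfft = 1 << int(np.ceil(np.log2(pad_factor * n)))
    X = np.fft.rfft(xw, nfft)
    S = (np.abs(X) ** 2) / (trace.rate * n)
    S[1:-1] *= 2.0  # fold negative frequencies; DC and Nyquist appear once
    f = np.fft.rfftfreq(nfft, d=1.0 / trace.rate)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise FeatureError("search band outside the spectrum's frequency grid")
    fc = float(f[mask][np.argmax(S[mask])])
    return SpectrumEstimate(f=f, S=S, fc=fc)


def _band_power(f: np.ndarray, S: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of S over [lo, hi] with interpolated endpoints."""
    lo = max(lo, float(f[0]))
    hi = min(hi, float(f[-1]))
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    ff = np.concatenate(([lo], f[inner], [hi]))
    SS = np.concatenate(([np.interp(lo, f, S)], S[inner], [np.interp(hi, f, S)]))
    return float(np.trapezoid(SS, ff))


def spcr(
    spec: SpectrumEstimate, narrow: float = 0.5, wide: float = 2.0
) -> float:
    """Signal power concentration ratio around the spectral peak.

    Power within ``fc +/- narrow`` divided by power within ``fc +/- wide``;
    a fraction in (0, 1], near 1 when the tremor is spectrally pure.
    """
    if narrow >= wide:
        raise FeatureError("narrow band must be smaller than wide band")
    denom = _band_power(spec.f, spec.S, spec.fc - wide, spec.fc + wide)
    if denom <= 0:
        raise FeatureError("degenerate spectrum: no power around the peak")
    num = _band_power(spec.f, spec.S, spec.fc - narrow, spec.fc + narrow)
    return num / denom


# Summaries and the full chain ---------------------------------------------


def summarize(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, sample std, interquartile range) of a series.

    Std uses the n-1 denominator; IQR uses linear-interpolation quantiles.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise FeatureError("cannot summarize an empty series")
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0
    q1, q3 = np.percentile(values, [25, 75])
    return mean, std, float(q3 - q1)


def extract_features(
    rec: GyroRecording, config: PipelineConfig | None = None
) -> FeatureSet:
    """Run the full chain on one recording and return its feature vector.

    trim -> high-pass detrend -> PCA -> autocorrelation f_ac -> band-pass ->
    peaks -> cycle series summaries + spectral peak + SPCR.  Deterministic;
    stage failures are re-raised as :class:`PipelineStageError` naming the
    stage.
    """
    cfg = config or PipelineConfig()
    if rec.duration < 4.0:
        raise FeatureError("recording shorter than 4 s; features unreliable")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineStageError(name, exc) from exc

    trimmed = _stage("trim", trim_segments, rec, cfg.trim_fraction)
    detrended = _stage(
        "detrend", highpass_detrend, trimmed, cfg.detrend_cutoff, cfg.detrend_order
    )
    trace = _stage("pca", principal_axis, detrended)
    ac: AutocorrEstimate = _stage(
        "autocorr", autocorr_dominant_freq, trace, cfg.band, cfg.autocorr_peak_rule
    )
    banded = _stage(
        "bandpass",
        bandpass_around,
        trace,
        ac.f_ac,
        cfg.bp_half_width,
        cfg.bp_order,
    )
    peaks = _stage("peaks", detect_peaks, banded, ac.f_ac, cfg.peak_min_prom_frac)
    cycles = _stage("cycles", cycle_series, peaks)
    spec = _stage("spectrum", estimate_spectrum, banded, cfg.band)
    ratio = _stage("spcr", spcr, spec, cfg.spcr_narrow, cfg.spcr_wide)
    a_mean, a_std, a_iqr = summarize(cycles.A)
    r_mean, r_std, r_iqr = summarize(cycles.dT)
    if len(cycles.df) == 0:
        raise PipelineStageError("cycles", FeatureError("insufficient cycles for ICVF"))
    i_mean, i_std, i_iqr = summarize(cycles.df)
    return FeatureSet(
        peak_frequency=spec.fc,
        amplitude_mean=a_mean,
        amplitude_std=a_std,
        amplitude_iqr=a_iqr,
        regularity_mean=r_mean,
        regularity_std=r_std,
        regularity_iqr=r_iqr,
        icvf_mean=i_mean,
        icvf_std=i_std,
        icvf_iqr=i_iqr,
        spcr=ratio,
        f_ac=ac.f_ac,
        pc1_evr=trace.pc1_evr,
    )
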