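"""Per-step feature extraction: 16 time- and frequency-domain gait features.

Each detected step contributes one feature vector. Time-domain features
describe the intensity and smoothness of the swing; frequency-domain features
describe the spectral signature of the stride. The assignment of each feature
to its segmentation type:

========================  =========  ==========================================
feature                   segment    meaning
========================  =========  ==========================================
std, range, rms           Type I     dispersion / range of motion of the stride
angular_jerk              Type II    (1/2) * integral of (d2 omega/dt2)^2 dt —
                                     movement smoothness of the swing
normalized_jerk           Type II    angular jerk / swing duration
stride_similarity         Type I     DTW alignment cost vs the previous stride
                                     of the same leg (0 = identical)
step_time_s               peaks      current peak - previous contralateral peak
stride_time_s             Type I     current peak - previous same-leg peak
peak_height, peak_width_s Type II    mid-swing amplitude; half-power width
power_spectral_entropy    Type I     Shannon entropy of the normalized power
                                     spectrum, -sum P*ln(P + eps), eps = 0.001
principal_harmonic_*      Type I     dominant non-DC spectral line: frequency,
                                     amplitude, half-power width
weighted_power_spectral_  Type I     amplitude x frequency of the principal
peak                                 harmonic
low_power_frequency       Type I     fraction of spectral power below 2 Hz
                                     (the locomotor band)
========================  =========  ==========================================

Spectra use a 512-point zero-padded FFT of the mean-removed Type I slice
(rectangular window); the one-sided squared magnitude is normalized to unit
sum. The entropy uses the natural logarithm; any other base is a monotone
rescaling absorbed by the classifiers.

Missing-data policy: steps lacking a previous same-leg stride or a previous
contralateral peak (the first one or two steps of each leg) are dropped, not
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import StepSegment, detect_peaks, segment_steps
from .signal_io import TrialRecording

__all__ = [
    "FEATURE_COLUMNS",
    "METADATA_COLUMNS",
    "basic_stats",
    "angular_jerk",
    "normalized_jerk",
    "dtw_distance",
    "stride_similarity",
    "step_and_stride_times",
    "peak_geometry",
    "spectrum",
    "power_spectral_entropy",
    "principal_harmonic",
    "low_power_frequency",
    "extract_features",
    "trial_feature_table",
    "cohort_feature_table",
]

N_FFT = 512
ENTROPY_EPS = 1e-3
LOW_POWER_BAND_HZ = (0.0, 2.0)

#: fixed feature-matrix schema (order matches the extraction table above)
FEATURE_COLUMNS = [
    "std",
    "range",
    "rms",
    "angular_jerk",
    "normalized_jerk",
    "stride_similarity",
    "step_time_s",
    "stride_time_s",
    "peak_height",
    "peak_width_s",
    "power_spectral_entropy",
    "principal_harmonic_freq_hz",
    "principal_harmonic_amp",
    "principal_harmonic_width_hz",
    "weighted_power_spectral_peak",
    "low_power_frequency",
]

METADATA_COLUMNS = ["subject_id", "condition", "trial_id", "leg", "peak_time_s"]


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------


def basic_stats(type1_slice: np.ndarray) -> tuple[float, float, float]:
    """Population standard deviation, range and RMS of a Type I slice."""
    x = np.asarray(type1_slice, dtype=float)
    if x.size < 2:
        raise FeatureError("slice too short for basic statistics")
    return (
        float(np.std(x)),
        float(np.max(x) - np.min(x)),
        float(np.sqrt(np.mean(x * x))),
    )


def angular_jerk(type2_slice: np.ndarray, sample_rate_hz: float) -> float:
    """Half the integral of the squared second derivative of angular velocity.

    The second derivative is estimated with central second differences scaled
    by the squared sampling rate; the integral is a trapezoid over the slice
    duration. Represents the rate of variation of the angular acceleration;
    smoother swings give smaller values.
    """
    x = np.asarray(type2_slice, dtype=float)
    if x.size < 3:
        raise FeatureError("slice too short for a second difference")
    acc2 = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * sample_rate_hz**2
    return 0.5 * float(np.trapezoid(acc2 * acc2, dx=1.0 / sample_rate_hz))


def normalized_jerk(type2_slice: np.ndarray, sample_rate_hz: float) -> float:
    """Angular jerk divided by the duration over which it is computed."""
    x = np.asarray(type2_slice, dtype=float)
    duration = (x.size - 1) / sample_rate_hz
    if duration <= 0:
        raise FeatureError("slice duration must be positive")
    return angular_jerk(x, sample_rate_hz) / duration


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping alignment cost between two sequences.

    Absolute-difference local cost, the standard match/insert/delete step
    pattern, no warping-window constraint. Zero iff the sequences are
    identical; symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise FeatureError("DTW inputs must be non-empty")
    m = b.size
    prev = np.empty(m + 1)
    prev[:] = np.inf
    prev[0] = 0.0
    cur = np.empty(m + 1)
    for i in range(a.size):
        cur[0] = np.inf
        ai = a[i]
        for j in range(1, m + 1):
            c = abs(ai - b[j - 1])
            cur[j] = c + min(prev[j], cur[j - 1], prev[j - 1])
        prev, cur = cur, prev
    return float(prev[m])


def stride_similarity(type1_now: np.ndarray, type1_prev: np.ndarray) -> float:
    """DTW cost between the current and previous same-leg Type I slices.

    The output grows as the strides diverge (it is *inversely* proportional
    to their similarity); regular gait gives values near zero.
    """
    return dtw_distance(type1_now, type1_prev)


def step_and_stride_times(segment: StepSegment) -> tuple[float | None, float | None]:
    """Step time (vs previous contralateral peak) and stride time (same leg)."""
    step = (
        segment.peak_time_s - segment.prev_contralateral_peak_time_s
        if segment.prev_contralateral_peak_time_s is not None
        else None
    )
    stride = (
        segment.peak_time_s - segment.prev_peak_time_s
        if segment.prev_peak_time_s is not None
        else None
    )
    return step, stride


def peak_geometry(
    type2_slice: np.ndarray, sample_rate_hz: float
) -> tuple[float, float]:
    """Height (vs zero) and half-power width of the positive swing lobe.

    The width is the time the lobe spends above ``height / sqrt(2)`` (the
    amplitude half-power point), with the threshold crossings located by
    linear interpolation.
    """
    x = np.asarray(type2_slice, dtype=float)
    height = float(np.max(x))
    if height <= 0:
        raise FeatureError("type II slice has no positive content")
    thr = height / math.sqrt(2.0)
    peak = int(np.argmax(x))
    # walk to the crossings on each side of the maximum
    left = 0.0
    for i in range(peak, 0, -1):
        if x[i - 1] < thr:
            left = (i - 1) + (thr - x[i - 1]) / (x[i] - x[i - 1])
            break
    else:
        left = 0.0
    right = float(x.size - 1)
    for i in range(peak, x.size - 1):
        if x[i + 1] < thr:
            right = i + (x[i] - thr) / (x[i] - x[i + 1])
            break
    return height, (right - left) / sample_rate_hz


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------


def spectrum(
    type1_slice: np.ndarray,
    sample_rate_hz: float,
    n_fft: int = N_FFT,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided normalized power spectrum of a mean-removed Type I slice.

    Returns ``(P, freqs)`` with ``sum(P) == 1``. The slice is zero-padded to
    ``n_fft`` points (rectangular window), which stabilizes the location of
    the spectral maximum for ~1 s strides at 60 Hz.
    """
    x = np.asarray(type1_slice, dtype=float)
    if x.size < 4:
        raise FeatureError("slice too short for a spectrum")
    x = x - np.mean(x)
    if not np.any(np.abs(x) > 0):
        raise FeatureError("all-zero slice after mean removal: spectrum undefined")
    spec = np.abs(np.fft.rfft(x, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    return spec / spec.sum(), freqs


def _check_normalized(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if abs(P.sum() - 1.0) > 1e-6:
        raise FeatureError("power spectrum must be normalized to unit sum")
    return P


def power_spectral_entropy(P: np.ndarray, eps: float = ENTROPY_EPS) -> float:
    """Spectral Shannon entropy ``-sum P * ln(P + eps)`` (natural log).

    The small ``eps`` keeps the logarithm finite on empty bins; it makes the
    entropy of a single-line spectrum slightly negative rather than zero.
    """
    P = _check_normalized(P)
    return float(-np.sum(P * np.log(P + eps)))


def principal_harmonic(
    P: np.ndarray, freqs: np.ndarray
) -> tuple[float, float, float, float]:
    """Dominant non-DC spectral line: (freq, amplitude, half-power width,
    amplitude x frequency).

    The half-power width is the frequency span over which the spectrum stays
    above half the line's power, with interpolated crossings (the spectrum is
    already a power quantity, so the threshold is ``amplitude / 2``).
    """
    P = _check_normalized(P)
    if P.size < 2 or not np.any(P[1:] > 0):
        raise FeatureError("spectrum has no non-DC content")
    i = 1 + int(np.argmax(P[1:]))
    amp = float(P[i])
    freq = float(freqs[i])
    thr = amp / 2.0
    df = float(freqs[1] - freqs[0])
    for j in range(i, 0, -1):
        if P[j - 1] < thr:
            lo = freqs[j - 1] + df * (thr - P[j - 1]) / (P[j] - P[j - 1])
            break
    else:
        lo = float(freqs[0])
    hi = float(freqs[i] + df)
    for j in range(i, P.size - 1):
        if P[j + 1] < thr:
            hi = freqs[j] + df * (P[j] - thr) / (P[j] - P[j + 1])
            break
    else:
        hi = float(freqs[-1])
    return freq, amp, float(hi - lo), amp * freq


def low_power_frequency(
    P: np.ndarray,
    freqs: np.ndarray,
    band_hz: tuple[float, float] = LOW_POWER_BAND_HZ,
) -> float:
    """Fraction of total spectral power inside the 0–2 Hz locomotor band."""
    P = _check_normalized(P)
    lo, hi = band_hz
    return float(P[(freqs >= lo) & (freqs <= hi)].sum())


# ---------------------------------------------------------------------------
# Per-step assembly
# ---------------------------------------------------------------------------


def extract_features(
    segment: StepSegment, sample_rate_hz: float, n_fft: int = N_FFT
) -> dict[str, float] | None:
    """Compute all 16 features for one step.

    Returns ``None`` when the missing-data policy applies (no previous
    same-leg stride or no previous contralateral peak), so the caller simply
    drops the step.
    """
    if segment.prev_type1 is None:
        return None
    step_time, stride_time = step_and_stride_times(segment)
    if step_time is None or stride_time is None:
        return None
    if segment.type1.size < 4 or segment.type2.size < 3:
        return None
    sd, rng_, rms = basic_stats(segment.type1)
    try:
        P, freqs = spectrum(segment.type1, sample_rate_hz, n_fft)
    except FeatureError:
        return None
    ph_freq, ph_amp, ph_width, weighted = principal_harmonic(P, freqs)
    height, width = peak_geometry(segment.type2, sample_rate_hz)
    return {
        "std": sd,
        "range": rng_,
        "rms": rms,
        "angular_jerk": angular_jerk(segment.type2, sample_rate_hz),
        "normalized_jerk": normalized_jerk(segment.type2, sample_rate_hz),
        "stride_similarity": stride_similarity(segment.type1, segment.prev_type1),
        "step_time_s": step_time,
        "stride_time_s": stride_time,
        "peak_height": height,
        "peak_width_s": width,
        "power_spectral_entropy": power_spectral_entropy(P),
        "principal_harmonic_freq_hz": ph_freq,
        "principal_harmonic_amp": ph_amp,
        "principal_harmonic_width_hz": ph_width,
        "weighted_power_spectral_peak": weighted,
        "low_power_frequency": low_power_frequency(P, freqs),
    }


def trial_feature_table(trial: TrialRecording, n_fft: int = N_FFT) -> pd.DataFrame:
    """Detect, segment and featurize both legs of one synchronized trial.

    Returns one row per retained step with the 16 feature columns plus
    metadata (subject, condition, trial, leg, peak time). Rows are sorted by
    peak time; steps dropped by the missing-data policy are absent, so the
    table contains no undefined values.
    """
    fs = trial.sample_rate_hz
    peaks = {
        leg: detect_peaks(trial.trace(leg), start_time_s=trial.gait_start_s)
        for leg in ("left", "right")
    }
    rows = []
    for leg, other in (("left", "right"), ("right", "left")):
        for seg in segment_steps(trial.trace(leg), peaks[leg], peaks[other]):
            feats = extract_features(seg, fs, n_fft)
            if feats is None:
                continue
            feats.update(
                subject_id=trial.subject_id,
                condition=trial.condition,
                trial_id=trial.trial_id,
                leg=leg,
                peak_time_s=seg.peak_time_s,
            )
            rows.append(feats)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS + METADATA_COLUMNS)
    return df.sort_values("peak_time_s", kind="stable").reset_index(drop=True)


def cohort_feature_table(trials) -> pd.DataFrame:
    """Concatenate per-trial feature tables for a list of recordings."""
    tables = [trial_feature_table(t) for t in trials]
    return pd.concat(tables, ignore_index=True)
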