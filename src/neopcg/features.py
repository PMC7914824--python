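"""Per-cycle feature extraction for segmented heart sounds.

Each segmented heartbeat cycle yields exactly 200 named features at the
2 kHz analysis rate:

* an energy/spectral block computed on all four intervals (S1, m1, S2, m2):
  raw energy and zero-crossing count, energy/RMS in linear and dB scale for
  the 25-1000 Hz wide band and for the five sub-bands 25-45, 45-80, 80-200,
  200-400 and 400-1000 Hz, the sub-200 Hz spectral centroid, its deviation
  from the per-point average centroid in octaves, and the interval's length
  relative to the point's mean cycle length (29 features x 4 intervals);
* a transient-morphology block on S1 and S2 only: absolute extrema and
  their normalised times, local-extrema and zero-crossing timing statistics,
  derivative-discontinuity count and max-position skewness (22 x 2);
* a murmur-oriented block on the silent intervals m1 and m2 only: envelope
  polynomial coefficients, quarter-wise energy/mean/sd profiles, whole
  interval mean/sd, zeros per second and max-position skewness (19 x 2);
* two per-point globals: beats per minute and the cycle's length relative
  to the point mean.

Murmurs live in the silent intervals, which is why the sub-band energy
features of m1/m2 carry most of the diagnostic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .io import ANALYSIS_RATE, INTERVAL_NAMES, AudioRecording, SegmentationAnnotation

DB_EPS = 1e-12  # dB floor: 10*log10(1e-12) = -120 dB

WIDE_BAND = (25.0, 1000.0)
SUB_BANDS = ((25.0, 45.0), (45.0, 80.0), (80.0, 200.0), (200.0, 400.0), (400.0, 1000.0))
FILTER_ORDER = 4
ENVELOPE_SMOOTH_S = 0.010  # moving-average window for the analytic envelope
NBROKEN_K = 4.0  # MAD multiplier for derivative-discontinuity detection

_TABLE2_TAGS = (
    ["energy", "n_zero", "bw_en_lin", "bw_en_db", "bw_rms_lin", "bw_rms_db"]
    + [f"b{k}_{m}" for k in range(1, 6) for m in ("en_lin", "en_db", "rms_lin", "rms_db")]
    + ["fc", "oct", "trel"]
)

_TABLE3_TAGS = [
    "a_max", "t_max", "a_min", "t_min", "max_a", "max_t",
    "mean_t_max", "mean_dt_max", "std_t_max", "std_dt_max", "n_max",
    "mean_t_min", "mean_dt_min", "std_t_min", "std_dt_min", "n_min",
    "mean_t_zero", "std_t_zero", "mean_dt_zero", "std_dt_zero",
    "n_broken", "skewness",
]

_TABLE4_TAGS = [
    "a0", "a1", "a2",
    "en_q1", "en_q2", "en_q3", "en_q4",
    "mean", "std",
    "mean_q1", "mean_q2", "mean_q3", "mean_q4",
    "std_q1", "std_q2", "std_q3", "std_q4",
    "frq_zero", "skewness",
]


def _build_feature_names() -> list[str]:
    names: list[str] = []
    for interval in INTERVAL_NAMES:
        names += [f"{interval}_{tag}" for tag in _TABLE2_TAGS]
    for interval in ("S1", "S2"):
        names += [f"{interval}_{tag}" for tag in _TABLE3_TAGS]
    for interval in ("m1", "m2"):
        names += [f"{interval}_{tag}" for tag in _TABLE4_TAGS]
    names += ["bpm", "cycle_trel"]
    return names


FEATURE_NAMES: list[str] = _build_feature_names()
assert len(FEATURE_NAMES) == 200 and len(set(FEATURE_NAMES)) == 200

META_COLUMNS = ["patient_id", "point_id", "cycle_index", "label"]


@dataclass(frozen=True)
class PointContext:
    """Per-auscultation-point references used by relative features."""

    mean_cycle_duration: float  # seconds
    mean_fc: dict[str, float]  # per interval name, Hz

    def __post_init__(self) -> None:
        if self.mean_cycle_duration <= 0:
            raise ValueError("mean_cycle_duration must be positive")

    @property
    def bpm(self) -> float:
        return 60.0 / self.mean_cycle_duration


# ---------------------------------------------------------------------------
# primitive operators
# ---------------------------------------------------------------------------

_SOS_CACHE: dict[tuple[float, float, float], np.ndarray] = {}


def _band_sos(lo: float, hi: float, rate: float) -> np.ndarray:
    key = (lo, hi, rate)
    sos = _SOS_CACHE.get(key)
    if sos is None:
        nyq = rate / 2.0
        if hi >= nyq and lo <= 0:
            raise ValueError("band covers the whole spectrum; nothing to filter")
        if hi >= nyq:
            sos = butter(FILTER_ORDER, lo / nyq, btype="highpass", output="sos")
        elif lo <= 0:
            sos = butter(FILTER_ORDER, hi / nyq, btype="lowpass", output="sos")
        else:
            sos = butter(FILTER_ORDER, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
        _SOS_CACHE[key] = sos
    return sos


def bandpass_filter(x: np.ndarray, rate: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass; output length = input length.

    A band reaching the Nyquist frequency degrades to a high-pass at ``lo``
    (the 400-1000 Hz band at the 2 kHz analysis rate); ``lo <= 0`` degrades
    to a low-pass at ``hi``.
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    x = np.asarray(x, dtype=np.float64)
    sos = _band_sos(float(lo), float(hi), float(rate))
    padlen = min(3 * (2 * sos.shape[0] + 1), len(x) - 1)
    return sosfiltfilt(sos, x, padlen=max(padlen, 0))


def energy_and_rms(x: np.ndarray) -> tuple[float, float, float, float]:
    """(energy, rms, energy_db, rms_db) with energy = sum of squares."""
    x = np.asarray(x, dtype=np.float64)
    energy = float(np.sum(x * x))
    rms = float(np.sqrt(energy / len(x)))
    return energy, rms, 10.0 * np.log10(energy + DB_EPS), 10.0 * np.log10(rms + DB_EPS)


def zero_crossing_count(x: np.ndarray) -> int:
    """Sign changes between consecutive samples; a zero sample separating
    opposite strict signs counts as one crossing."""
    s = np.sign(np.asarray(x, dtype=np.float64))
    nz = s[s != 0]
    if len(nz) < 2:
        return 0
    return int(np.count_nonzero(np.diff(nz)))


def _zero_crossing_positions(x: np.ndarray) -> np.ndarray:
    """Indices i such that a crossing occurs between the previous non-zero
    sample and sample i (i is the right edge of the crossing)."""
    s = np.sign(np.asarray(x, dtype=np.float64))
    positions = []
    last_sign = 0.0
    for i, si in enumerate(s):
        if si == 0:
            continue
        if last_sign != 0 and si != last_sign:
            positions.append(i)
        last_sign = si
    return np.asarray(positions, dtype=np.int64)


def spectral_centroid_0_200(x: np.ndarray, rate: float) -> float:
    """Magnitude-weighted mean frequency over DFT bins in (0, 200] Hz.

    The DC bin is excluded; returns 0 when no in-band magnitude remains
    (constant or empty-band signals).
    """
    x = np.asarray(x, dtype=np.float64)
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    mask = (freqs > 0) & (freqs <= 200.0)
    weights = spectrum[mask]
    total = weights.sum()
    if total < DB_EPS:
        return 0.0
    return float(np.sum(freqs[mask] * weights) / total)


def octave_deviation(fc: float, fc_ref: float) -> float:
    """log2(fc / fc_ref); 0 for degenerate fc <= 0."""
    if fc_ref <= 0:
        raise ValueError("fc_ref must be positive")
    if fc <= 0:
        return 0.0
    return float(np.log2(fc / fc_ref))


def signal_envelope(x: np.ndarray, rate: float = ANALYSIS_RATE) -> np.ndarray:
    """Magnitude of the analytic signal smoothed by a 10 ms moving average."""
    env = np.abs(hilbert(np.asarray(x, dtype=np.float64)))
    win = max(int(round(ENVELOPE_SMOOTH_S * rate)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        env = np.convolve(np.pad(env, (win // 2, win - 1 - win // 2), mode="edge"),
                          kernel, mode="valid")
    return env


def envelope_poly_coeffs(x: np.ndarray, rate: float = ANALYSIS_RATE) -> tuple[float, float, float]:
    """Least-squares fit a0 + a1*t + a2*t^2 to the envelope, t in [0, 1]."""
    env = signal_envelope(x, rate)
    t = np.linspace(0.0, 1.0, len(env))
    coeffs = np.polynomial.polynomial.polyfit(t, env, 2)
    return float(coeffs[0]), float(coeffs[1]), float(coeffs[2])


def _local_extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima/minima; a plateau counts once at its first sample."""
    x = np.asarray(x, dtype=np.float64)
    maxima, minima = [], []
    n = len(x)
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        # plateau (possibly width 1) from i..j; neighbours i-1 and j+1
        if j < n - 1:
            left, mid, right = x[i - 1], x[i], x[j + 1]
            if mid > left and mid > right:
                maxima.append(i)
            elif mid < left and mid < right:
                minima.append(i)
        i = j + 1
    return np.asarray(maxima, dtype=np.int64), np.asarray(minima, dtype=np.int64)


def _timing_stats(indices: np.ndarray, n: int) -> tuple[float, float, float, float]:
    """(mean_t, mean_dt, std_t, std_dt) of normalised event times; 0 when
    undefined (fewer than 1 event for t-stats, fewer than 2 for dt-stats)."""
    if len(indices) == 0:
        return 0.0, 0.0, 0.0, 0.0
    t = indices / n
    mean_t = float(np.mean(t))
    std_t = float(np.std(t))
    if len(indices) >= 2:
        dt = np.diff(t)
        mean_dt = float(np.mean(dt))
        std_dt = float(np.std(dt))
    else:
        mean_dt = std_dt = 0.0
    return mean_t, mean_dt, std_t, std_dt


def extrema_timing_stats(x: np.ndarray) -> dict[str, float]:
    """Absolute-extrema and local-extrema/zero-crossing timing statistics.

    Times are normalised by interval length; degenerate inputs (constant
    vectors, no events) yield 0 for the undefined statistics.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    out: dict[str, float] = {}
    imax = int(np.argmax(x))
    imin = int(np.argmin(x))
    iabs = int(np.argmax(np.abs(x)))
    denom = n - 1 if n > 1 else 1
    out["a_max"] = float(x[imax])
    out["t_max"] = imax / denom
    out["a_min"] = float(x[imin])
    out["t_min"] = imin / denom
    out["max_a"] = float(abs(x[iabs]))
    out["max_t"] = iabs / denom

    maxima, minima = _local_extrema_indices(x)
    for prefix, idx in (("max", maxima), ("min", minima)):
        mean_t, mean_dt, std_t, std_dt = _timing_stats(idx, n)
        out[f"mean_t_{prefix}"] = mean_t
        out[f"mean_dt_{prefix}"] = mean_dt
        out[f"std_t_{prefix}"] = std_t
        out[f"std_dt_{prefix}"] = std_dt
        out[f"n_{prefix}"] = float(len(idx))

    zeros = _zero_crossing_positions(x)
    mean_t, mean_dt, std_t, std_dt = _timing_stats(zeros, n)
    out["mean_t_zero"] = mean_t
    out["std_t_zero"] = std_t
    out["mean_dt_zero"] = mean_dt
    out["std_dt_zero"] = std_dt
    return out


def quarter_profile(x: np.ndarray) -> dict[str, float]:
    """Quarter-wise energy/mean/sd plus whole-interval mean/sd.

    The interval is split into 4 contiguous quarters of floor(n/4) samples;
    remainder samples go to the last quarter.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    q = n // 4
    edges = [0, q, 2 * q, 3 * q, n]
    out: dict[str, float] = {}
    for k in range(4):
        seg = x[edges[k]:edges[k + 1]]
        out[f"en_q{k + 1}"] = float(np.sum(seg * seg))
        out[f"mean_q{k + 1}"] = float(np.mean(seg))
        out[f"std_q{k + 1}"] = float(np.std(seg))
    out["mean"] = float(np.mean(x))
    out["std"] = float(np.std(x))
    return out


def position_skewness(x: np.ndarray) -> float:
    """Position of the max-|x| sample mapped to [-1, 1] around the midpoint."""
    x = np.asarray(x, dtype=np.float64)
    i = int(np.argmax(np.abs(x)))
    return 2.0 * i / (len(x) - 1) - 1.0


def derivative_discontinuity_count(x: np.ndarray) -> int:
    """Count isolated runs where |second difference| exceeds k*MAD.

    Robust to amplitude scale; a straight line or constant has zero
    second-difference spread and no discontinuities.
    """
    x = np.asarray(x, dtype=np.float64)
    d2 = np.diff(x, n=2)
    if len(d2) == 0:
        return 0
    dev = np.abs(d2 - np.median(d2))
    mad = float(np.median(dev))
    # floor keeps float jitter on perfectly smooth signals from counting
    atol = 1e-9 * max(float(np.max(np.abs(x))), 1.0)
    exceeds = dev > max(NBROKEN_K * mad, atol)
    if not np.any(exceeds):
        return 0
    # isolated runs of consecutive exceedances count once
    starts = np.flatnonzero(exceeds & ~np.concatenate(([False], exceeds[:-1])))
    return int(len(starts))


def frq_zero(x: np.ndarray, rate: float) -> float:
    """Zero crossings per second."""
    return zero_crossing_count(x) * float(rate) / len(x)


# ---------------------------------------------------------------------------
# full per-cycle vector
# ---------------------------------------------------------------------------

def _table2_block(x: np.ndarray, rate: float, interval: str,
                  duration: float, context: PointContext) -> dict[str, float]:
    out: dict[str, float] = {}
    energy, _, _, _ = energy_and_rms(x)
    out[f"{interval}_energy"] = energy
    out[f"{interval}_n_zero"] = float(zero_crossing_count(x))
    xw = bandpass_filter(x, rate, *WIDE_BAND)
    en, rms, en_db, rms_db = energy_and_rms(xw)
    out[f"{interval}_bw_en_lin"] = en
    out[f"{interval}_bw_en_db"] = en_db
    out[f"{interval}_bw_rms_lin"] = rms
    out[f"{interval}_bw_rms_db"] = rms_db
    for k, band in enumerate(SUB_BANDS, start=1):
        xb = bandpass_filter(x, rate, *band)
        en, rms, en_db, rms_db = energy_and_rms(xb)
        out[f"{interval}_b{k}_en_lin"] = en
        out[f"{interval}_b{k}_en_db"] = en_db
        out[f"{interval}_b{k}_rms_lin"] = rms
        out[f"{interval}_b{k}_rms_db"] = rms_db
    fc = spectral_centroid_0_200(x, rate)
    out[f"{interval}_fc"] = fc
    ref = context.mean_fc.get(interval, 0.0)
    out[f"{interval}_oct"] = octave_deviation(fc, ref) if ref > 0 else 0.0
    out[f"{interval}_trel"] = duration / context.mean_cycle_duration
    return out


def extract_cycle_features(samples, cycle, context: PointContext,
                           rate: float = ANALYSIS_RATE) -> dict[str, float]:
    """Compute the full 200-feature vector for one segmented cycle.

    ``samples`` is the recording the cycle boundaries index into, at the
    2 kHz analysis rate. Returns an ordered dict following FEATURE_NAMES.
    """
    samples = np.asarray(samples, dtype=np.float64)
    slices = cycle.interval_slices()
    intervals = {}
    for name, sl in slices.items():
        seg = samples[sl]
        if len(seg) < 2:
            raise ValueError(f"interval {name} shorter than 2 samples")
        intervals[name] = seg

    out: dict[str, float] = {}
    for name in INTERVAL_NAMES:
        seg = intervals[name]
        out.update(_table2_block(seg, rate, name, len(seg) / rate, context))
    for name in ("S1", "S2"):
        seg = intervals[name]
        stats = extrema_timing_stats(seg)
        for tag in _TABLE3_TAGS:
            if tag == "n_broken":
                out[f"{name}_{tag}"] = float(derivative_discontinuity_count(seg))
            elif tag == "skewness":
                out[f"{name}_{tag}"] = position_skewness(seg)
            else:
                out[f"{name}_{tag}"] = stats[tag]
    for name in ("m1", "m2"):
        seg = intervals[name]
        a0, a1, a2 = envelope_poly_coeffs(seg, rate)
        out[f"{name}_a0"], out[f"{name}_a1"], out[f"{name}_a2"] = a0, a1, a2
        profile = quarter_profile(seg)
        for tag, value in profile.items():
            out[f"{name}_{tag}"] = value
        out[f"{name}_frq_zero"] = frq_zero(seg, rate)
        out[f"{name}_skewness"] = position_skewness(seg)
    out["bpm"] = context.bpm
    out["cycle_trel"] = (cycle.n_samples / rate) / context.mean_cycle_duration
    ordered = {name: out[name] for name in FEATURE_NAMES}
    if len(ordered) != 200:
        raise AssertionError("feature census violated")
    return ordered


def point_context(samples, annotation: SegmentationAnnotation,
                  rate: float = ANALYSIS_RATE) -> PointContext:
    """Per-point references: mean cycle duration and mean spectral centroid
    per interval, over all cycles at the auscultation point."""
    samples = np.asarray(samples, dtype=np.float64)
    durations = [c.n_samples / rate for c in annotation.cycles]
    fc_acc: dict[str, list[float]] = {name: [] for name in INTERVAL_NAMES}
    for cyc in annotation.cycles:
        for name, sl in cyc.interval_slices().items():
            fc_acc[name].append(spectral_centroid_0_200(samples[sl], rate))
    mean_fc = {name: float(np.mean(v)) for name, v in fc_acc.items()}
    return PointContext(mean_cycle_duration=float(np.mean(durations)), mean_fc=mean_fc)


def extract_point_features(recording: AudioRecording,
                           annotation: SegmentationAnnotation) -> pd.DataFrame:
    """Feature rows for every cycle of one auscultation point.

    The recording is resampled to the analysis rate if needed and the
    annotation boundaries rescaled proportionally.
    """
    from .io import resample_recording

    if recording.rate != ANALYSIS_RATE:
        factor = ANALYSIS_RATE / recording.rate
        recording = resample_recording(recording, ANALYSIS_RATE)
        annotation = annotation.rescaled(factor)
    ctx = point_context(recording.samples, annotation)
    rows = []
    for idx, cyc in enumerate(annotation.cycles):
        row = {"patient_id": recording.patient_id, "point_id": recording.point_id,
               "cycle_index": idx}
        row.update(extract_cycle_features(recording.samples, cyc, ctx))
        rows.append(row)
    return pd.DataFrame(rows)


def extract_patient_features(patient) -> pd.DataFrame:
    """Feature rows for all points of a simulated/loaded patient record."""
    frames = []
    for point_id in sorted(patient.recordings):
        df = extract_point_features(patient.recordings[point_id],
                                    patient.segmentations[point_id])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(3, "label", patient.label)
    return out


def extract_cohort_features(patients) -> pd.DataFrame:
    """Feature table (one row per cycle) for a list of patient records."""
    return pd.concat([extract_patient_features(p) for p in patients],
                     ignore_index=True)


def save_features(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def load_features(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})
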