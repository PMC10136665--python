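"""ECG processing: QRS detection, RR correction, and heart-rate-variability features.

The chain mirrors standard short-term HRV practice for single-lead chest-strap
ECG: a Pan-Tompkins-style detector (band-pass, derivative, squaring, moving
integration, adaptive dual thresholds, refractory period) produces beat
times; intervals deviating from a local median are flagged and repaired; the
corrected series yields

* time-domain features  — HR, RMSSD, NN50;
* Poincare-plot indices — SD1, SD2, CSI = SD2/SD1, CVI = log10(SD1*SD2);
* spectral band powers  — LF (0.04-0.15 Hz), HF (0.15-0.4 Hz) and their ratio.

All intervals are in seconds; SD1/SD2 use the population (divide-by-N)
convention; CVI uses SD1*SD2 in s^2 (the millisecond convention adds +6).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    UnreliableSeriesError,
    UnusableRecordError,
    WindowTooShortError,
)

log = logging.getLogger(__name__)

# interval quality flags
FLAG_NORMAL = 0
FLAG_CORRECTED = 1
FLAG_REJECTED = 2

#: physiologically admissible RR interval range, seconds
RR_MIN, RR_MAX = 0.25, 3.0

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class ECGRecord:
    """Single-channel ECG: samples in millivolt at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        x = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ConfigurationError("ECG samples must be finite")
        object.__setattr__(self, "samples", x)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class RRSeries:
    """Beat times and inter-beat intervals with per-interval quality flags.

    ``intervals[i]`` spans ``beat_times[i] .. beat_times[i+1]``. After
    correction the flags record which intervals were repaired and
    ``fraction_corrected`` how many of the original intervals were touched.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    flags: np.ndarray
    fraction_corrected: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.intervals, dtype=float)
        fl = np.asarray(self.flags, dtype=np.int8)
        if len(rr) != len(t) - 1 or len(fl) != len(rr):
            raise ConfigurationError("intervals/flags must have len(beat_times) - 1")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ConfigurationError("beat times must be strictly increasing")
        if not (0.0 <= self.fraction_corrected <= 1.0):
            raise ConfigurationError("fraction_corrected must lie in [0, 1]")
        object.__setattr__(self, "beat_times", t)
        object.__setattr__(self, "intervals", rr)
        object.__setattr__(self, "flags", fl)

    @classmethod
    def from_beat_times(cls, beat_times: Sequence[float]) -> "RRSeries":
        t = np.asarray(beat_times, dtype=float)
        rr = np.diff(t)
        return cls(t, rr, np.zeros(len(rr), dtype=np.int8))

    @classmethod
    def from_intervals(cls, intervals: Sequence[float], t0: float = 0.0) -> "RRSeries":
        """Build a series whose stored intervals are exactly the given values
        (beat times are their cumulative sum; no diff round-off)."""
        rr = np.asarray(intervals, dtype=float)
        t = t0 + np.concatenate([[0.0], np.cumsum(rr)])
        return cls(t, rr, np.zeros(len(rr), dtype=np.int8))

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        """Boolean mask over intervals fully contained in the half-open window."""
        if window is None:
            return np.ones(len(self.intervals), dtype=bool)
        t0, t1 = window
        return (self.beat_times[:-1] >= t0) & (self.beat_times[1:] <= t1)

    def retained_mask(self) -> np.ndarray:
        return self.flags != FLAG_REJECTED


@dataclass
class HRVFeatureSet:
    """Cardiac features over one analysis window; NaN marks 'not computable'."""

    hr: float = math.nan          # beats/min
    rmssd: float = math.nan       # s
    nn50: float = math.nan        # count
    sd1: float = math.nan         # s
    sd2: float = math.nan         # s
    csi: float = math.nan         # SD2/SD1
    cvi: float = math.nan         # log10(SD1*SD2), s^2 convention
    lf: float = math.nan          # band power, s^2
    hf: float = math.nan          # band power, s^2
    lf_hf: float = math.nan       # raw power ratio
    lf_log10: float = math.nan
    hf_log10: float = math.nan

    #: column labels used in feature tables, in reporting order
    TABLE_NAMES = ("HR", "RMSSD", "NN50", "CSI", "CVI", "LF", "HF", "LF/HF")

    def to_dict(self) -> dict[str, float]:
        return {
            "HR": self.hr,
            "RMSSD": self.rmssd,
            "NN50": self.nn50,
            "CSI": self.csi,
            "CVI": self.cvi,
            "LF": self.lf,
            "HF": self.hf,
            "LF/HF": self.lf_hf,
        }

    def update(self, other: "HRVFeatureSet") -> "HRVFeatureSet":
        for name in (
            "hr", "rmssd", "nn50", "sd1", "sd2", "csi", "cvi",
            "lf", "hf", "lf_hf", "lf_log10", "hf_log10",
        ):
            v = getattr(other, name)
            if np.isfinite(v):
                setattr(self, name, v)
        return self


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

def detect_qrs(ecg: ECGRecord, refractory_s: float = 0.2) -> RRSeries:
    """Detect R peaks and return the uncorrected RR series.

    Pan-Tompkins-style chain: 5-15 Hz band-pass, derivative, squaring,
    150 ms moving-window integration, adaptive dual thresholds over
    candidate peaks, 200 ms refractory, with the final R location refined
    on the raw signal.

    Raises :class:`UnusableRecordError` for flat or saturated records and
    records shorter than 10 s.
    """
    if ecg.fs < 250:
        raise ConfigurationError("QRS detection requires a sampling rate >= 250 Hz")
    x = ecg.samples
    if ecg.duration < 10.0:
        raise UnusableRecordError("record shorter than 10 s")
    if np.ptp(x) < 1e-6 or np.std(x) < 1e-9:
        raise UnusableRecordError("flat ECG signal")
    lo, hi = np.min(x), np.max(x)
    rail = max(np.mean(np.isclose(x, lo)), np.mean(np.isclose(x, hi)))
    if rail > 0.2:
        raise UnusableRecordError("saturated ECG signal")

    fs = ecg.fs
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    min_dist = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(integ, distance=min_dist)
    if len(cand) < 2:
        raise UnusableRecordError("no QRS candidates found")

    # adaptive dual thresholds on the integrated signal
    spki = float(np.percentile(integ[cand], 90))
    npki = float(np.percentile(integ, 50))
    beats: list[int] = []
    for c in cand:
        p = integ[c]
        thr = npki + 0.25 * (spki - npki)
        if p > thr:
            beats.append(c)
            spki = 0.125 * p + 0.875 * spki
        else:
            npki = 0.125 * p + 0.875 * npki

    if len(beats) < 2:
        raise UnusableRecordError("fewer than 2 beats detected")

    # refine: local raw-signal maximum within +-150 ms of each candidate
    half = int(round(0.150 * fs))
    refined: list[int] = []
    for b in beats:
        a, z = max(0, b - half), min(len(x), b + half + 1)
        refined.append(a + int(np.argmax(x[a:z])))

    # dedupe peaks that collapsed onto the same R wave
    refined_arr = np.unique(np.asarray(refined))
    keep: list[int] = []
    for idx in refined_arr:
        if keep and (idx - keep[-1]) < min_dist:
            if x[idx] > x[keep[-1]]:
                keep[-1] = idx
        else:
            keep.append(idx)

    times = ecg.start_time + np.asarray(keep, dtype=float) / fs
    return RRSeries.from_beat_times(times)


# ---------------------------------------------------------------------------
# RR correction
# ---------------------------------------------------------------------------

def _local_median(rr: np.ndarray, i: int, window: int) -> float:
    half = window // 2
    lo = max(0, i - half)
    hi = min(len(rr), i + half + 1)
    neigh = np.concatenate([rr[lo:i], rr[i + 1 : hi]])
    if len(neigh) == 0:
        return float(rr[i])
    return float(np.median(neigh))


def correct_rr(
    rr: RRSeries,
    deviation_threshold: float = 0.20,
    window: int = 11,
    max_corrected_fraction: float = 0.20,
) -> RRSeries:
    """Flag and repair abnormal (non-sinus) intervals.

    An interval deviating more than ``deviation_threshold`` from the median
    of its ``window`` surrounding intervals is flagged: an interval near a
    multiple of the local median (missed beats) is split into equal parts, a
    short interval whose merge with its successor fits the local median
    (spurious beat) is merged, anything else is replaced by the local
    median. Beat times are rebuilt from the corrected intervals so they stay
    strictly increasing.

    Raises :class:`UnreliableSeriesError` when more than
    ``max_corrected_fraction`` of the original intervals needed repair.
    """
    rr_in = rr.intervals
    n = len(rr_in)
    if n < window + 1:
        raise InsufficientDataError(
            f"correction needs at least {window + 1} intervals, got {n}"
        )

    out: list[float] = []
    flags: list[int] = []
    n_touched = 0
    i = 0
    while i < n:
        v = rr_in[i]
        med = _local_median(rr_in, i, window)
        dev = abs(v - med) / med if med > 0 else np.inf
        if dev <= deviation_threshold and RR_MIN < v < RR_MAX:
            out.append(float(v))
            flags.append(FLAG_NORMAL)
            i += 1
            continue
        n_touched += 1
        if v > 1.5 * med:
            # missed beat(s): split into k near-median intervals
            k = max(2, int(round(v / med)))
            out.extend([float(v / k)] * k)
            flags.extend([FLAG_CORRECTED] * k)
            i += 1
        elif (
            v < 0.5 * med
            and i + 1 < n
            and abs((v + rr_in[i + 1]) - med) / med <= deviation_threshold
        ):
            # spurious beat: merge with successor
            out.append(float(v + rr_in[i + 1]))
            flags.append(FLAG_CORRECTED)
            n_touched += 1
            i += 2
        else:
            out.append(float(med))
            flags.append(FLAG_CORRECTED)
            i += 1

    frac = n_touched / n
    if frac > max_corrected_fraction:
        raise UnreliableSeriesError(
            f"{frac:.0%} of intervals required correction "
            f"(ceiling {max_corrected_fraction:.0%})"
        )
    if frac > 0:
        log.info("RR correction touched %.1f%% of intervals", 100 * frac)

    t0 = rr.beat_times[0]
    times = np.concatenate([[t0], t0 + np.cumsum(out)])
    return RRSeries(
        beat_times=times,
        intervals=np.asarray(out),
        flags=np.asarray(flags, dtype=np.int8),
        fraction_corrected=frac,
    )


# ---------------------------------------------------------------------------
# Time-domain features
# ---------------------------------------------------------------------------

def _successive_diffs(rr: RRSeries, mask: np.ndarray) -> np.ndarray:
    """Differences of adjacent interval pairs where both are flagged normal."""
    ok = mask & (rr.flags == FLAG_NORMAL)
    pair = ok[:-1] & ok[1:]
    return rr.intervals[1:][pair] - rr.intervals[:-1][pair]


def time_domain_features(
    rr: RRSeries, window: tuple[float, float] | None = None
) -> HRVFeatureSet:
    """HR, RMSSD and NN50 over a window.

    HR uses all retained (normal + corrected) intervals; RMSSD and NN50 use
    only pairs of adjacent normal intervals, so repaired beats never enter
    the difference statistics. NN50 counts differences strictly greater
    than 50 ms.
    """
    mask = rr.window_mask(window) & rr.retained_mask()
    vals = rr.intervals[mask]
    if len(vals) < 3:
        raise InsufficientDataError(
            f"time-domain features need >= 3 usable intervals, got {len(vals)}"
        )
    out = HRVFeatureSet()
    out.hr = 60.0 / float(np.mean(vals))
    d = _successive_diffs(rr, rr.window_mask(window))
    if len(d) >= 1:
        out.rmssd = float(np.sqrt(np.mean(d**2)))
        # strict inequality; the epsilon keeps float representations of an
        # exact 50 ms tie (e.g. 0.85 - 0.80) from counting
        out.nn50 = float(np.sum(np.abs(d) > 0.050 + 1e-12))
    return out


# ---------------------------------------------------------------------------
# Poincare features
# ---------------------------------------------------------------------------

def poincare_features(
    rr: RRSeries, window: tuple[float, float] | None = None, units: str = "s"
) -> HRVFeatureSet:
    """SD1, SD2, CSI and CVI from the Poincare plot of (RR_i, RR_{i+1}).

    SD1 and SD2 are the population standard deviations of the scatter
    projected on the lines perpendicular and parallel to the identity,
    i.e. of (RR_{i+1} - RR_i)/sqrt(2) and (RR_{i+1} + RR_i)/sqrt(2).
    CSI = SD2/SD1 and CVI = log10(SD1*SD2) are undefined (NaN) when either
    dispersion vanishes. ``units='ms'`` switches CVI to the millisecond
    convention (adds 6 to the s^2 value).
    """
    if units not in ("s", "ms"):
        raise ConfigurationError("units must be 's' or 'ms'")
    mask = rr.window_mask(window) & (rr.flags == FLAG_NORMAL)
    pair = mask[:-1] & mask[1:]
    x = rr.intervals[:-1][pair]
    y = rr.intervals[1:][pair]
    if len(x) < 3:
        raise InsufficientDataError(
            f"Poincare features need >= 4 normal intervals, got {len(x) + 1}"
        )
    out = HRVFeatureSet()
    out.sd1 = float(np.std((y - x) / np.sqrt(2.0)))
    out.sd2 = float(np.std((y + x) / np.sqrt(2.0)))
    # dispersions at float round-off level are genuinely zero
    noise_floor = 1e-12 * float(np.mean(x))
    out.sd1 = 0.0 if out.sd1 < noise_floor else out.sd1
    out.sd2 = 0.0 if out.sd2 < noise_floor else out.sd2
    if out.sd1 > 0 and out.sd2 > 0:
        out.csi = out.sd2 / out.sd1
        scale = 1e6 if units == "ms" else 1.0
        out.cvi = float(np.log10(out.sd1 * out.sd2 * scale))
    return out


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def _tachogram(rr: RRSeries, window: tuple[float, float] | None):
    mask = rr.window_mask(window) & rr.retained_mask()
    t = rr.beat_times[1:][mask]  # interval stamped at its closing beat
    v = rr.intervals[mask]
    return t, v


def spectral_features(
    rr: RRSeries,
    window: tuple[float, float] | None = None,
    mode: str = "welch",
    fs_resample: float = 4.0,
) -> HRVFeatureSet:
    """LF/HF band powers of the RR tachogram.

    ``mode='welch'`` (default, windows >= 60 s): the tachogram is resampled
    at ``fs_resample`` by cubic interpolation (linear for < 8 beats),
    linearly detrended, and the power spectral density estimated by Welch's
    averaged periodogram; LF and HF integrate the density over
    0.04-0.15 Hz and 0.15-0.4 Hz.

    ``mode='lombscargle'`` (short stimulus windows): a Lomb-Scargle
    periodogram over the uneven beat pairs, normalised so that total power
    over 0.01-0.5 Hz equals the tachogram variance. A 10 s window cannot
    resolve 0.04 Hz content; this is logged, not raised.

    LF/HF is always the ratio of raw band powers; log10 powers are reported
    alongside because tabulated HRV spectra are often log-scaled.
    """
    t, v = _tachogram(rr, window)
    if window is not None:
        span = window[1] - window[0]
    else:
        span = rr.beat_times[-1] - rr.beat_times[0]
    if mode == "welch" and span < 60.0:
        raise WindowTooShortError(
            f"welch mode needs a window >= 60 s (got {span:.1f} s); "
            "use mode='lombscargle' for stimulus-length windows"
        )
    if len(v) < 4:
        raise InsufficientDataError("spectral features need >= 4 usable intervals")

    out = HRVFeatureSet()
    if np.ptp(v) == 0:
        out.lf = 0.0
        out.hf = 0.0
        return out

    if mode == "welch":
        grid = np.arange(t[0], t[-1], 1.0 / fs_resample)
        if len(v) >= 8:
            y = CubicSpline(t, v)(grid)
        else:
            y = np.interp(grid, t, v)
        y = sps.detrend(y, type="linear")
        nper = min(len(y), int(256 * fs_resample / 4.0))
        freqs, psd = sps.welch(y, fs=fs_resample, nperseg=nper)
        lf = _band_power(freqs, psd, LF_BAND)
        hf = _band_power(freqs, psd, HF_BAND)
    elif mode == "lombscargle":
        if span < 1.5 / LF_BAND[0]:
            log.info(
                "window of %.0f s cannot resolve %.2f Hz content; "
                "LF from Lomb-Scargle is indicative only", span, LF_BAND[0]
            )
        y = v - np.mean(v)
        freqs = np.arange(0.01, 0.5, 0.005)
        pgram = sps.lombscargle(t, y, 2 * np.pi * freqs)
        total = np.trapezoid(pgram, freqs)
        scale = np.var(y) / total if total > 0 else 0.0
        psd = pgram * scale
        lf = _band_power(freqs, psd, LF_BAND)
        hf = _band_power(freqs, psd, HF_BAND)
    else:
        raise ConfigurationError(f"unknown spectral mode {mode!r}")

    out.lf = lf
    out.hf = hf
    if hf > 0:
        out.lf_hf = lf / hf
    if lf > 0:
        out.lf_log10 = float(np.log10(lf))
    if hf > 0:
        out.hf_log10 = float(np.log10(hf))
    return out


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    m = (freqs >= band[0]) & (freqs <= band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def hrv_features(
    rr: RRSeries,
    window: tuple[float, float] | None = None,
    spectral_mode: str = "welch",
) -> HRVFeatureSet:
    """All cardiac features over one window of a corrected RR series.

    Features whose preconditions fail are left NaN rather than aborting the
    window (a stimulus window is too short for Welch spectra, a near-empty
    window has too few beats, ...).
    """
    out = HRVFeatureSet()
    try:
        out.update(time_domain_features(rr, window))
    except InsufficientDataError:
        return out
    try:
        out.update(poincare_features(rr, window))
    except InsufficientDataError:
        pass
    try:
        out.update(spectral_features(rr, window, mode=spectral_mode))
    except (InsufficientDataError, WindowTooShortError):
        pass
    return out


def extract_hrv(
    ecg: ECGRecord,
    windows: Sequence[tuple[float, float]],
    deviation_threshold: float = 0.20,
    spectral_mode: str = "welch",
) -> list[HRVFeatureSet]:
    """detect -> correct -> features for each analysis window."""
    rr = correct_rr(detect_qrs(ecg), deviation_threshold=deviation_threshold)
    return [hrv_features(rr, w, spectral_mode=spectral_mode) for w in windows]
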