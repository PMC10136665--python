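"""Synthetic cohorts of paired (T0, T1) wearable recording sessions.

Generates raw ECG and skin-conductance signals with retained ground truth so
every downstream stage has a parameter-recovery test:

* RR series  — mean rate plus white per-beat noise plus two band-limited
  Gaussian modulations confined to the LF (0.04-0.15 Hz) and HF
  (0.15-0.4 Hz) bands, partitioning variance the same way the cardiac
  features do;
* ECG        — a stylised biphasic R-dominant template (80 ms support)
  placed at each beat time plus additive white noise;
* GSR        — a slowly drifting tonic level plus stimulus-locked Bateman
  responses plus noise, the generative inverse of the decomposition.

Session structure follows the study protocol (3' baseline, 10 x 10 s odor
stimuli at 30 s inter-stimulus interval, 3' recovery), with T1 parameters
obtained from T0 by additive per-subject effect deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .ecg import ECGRecord, RRSeries
from .eda import EDARecord, impulse_response, TAU_RISE_DEFAULT, TAU_DECAY_DEFAULT
from .errors import ConfigurationError
from .protocol import PHASES, SessionProtocol

HR_MIN, HR_MAX = 30.0, 220.0

#: ECG template support, seconds
_TEMPLATE_HALF_S = 0.040


def _validate(name: str, value: float, lo: float, hi: float) -> float:
    v = float(value)
    if not np.isfinite(v) or not (lo <= v <= hi):
        raise ConfigurationError(f"{name}={value!r} outside [{lo}, {hi}]")
    return v


# ---------------------------------------------------------------------------
# RR series
# ---------------------------------------------------------------------------

def _band_limited_noise(
    n: int, fs: float, band: tuple[float, float], power: float, rng: np.random.Generator
) -> np.ndarray:
    """FFT-filtered white noise confined to ``band`` with variance ``power``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    if sd > 0:
        x *= np.sqrt(power) / sd
    return x


def simulate_rr_series(
    mean_hr: float,
    sd_scale: float,
    lf_power: float,
    hf_power: float,
    duration: float,
    seed: int | np.random.Generator,
    start_time: float = 0.0,
) -> RRSeries:
    """Beat times spanning ``[0, duration]`` with a prescribed variability mix.

    ``sd_scale`` (s) is the standard deviation of i.i.d. per-beat noise, so
    the population RMSSD of a pure white series is ``sd_scale * sqrt(2)``;
    ``lf_power``/``hf_power`` (s^2) are the variances of the two
    band-limited modulations sampled at the beat times.
    """
    mean_hr = _validate("mean_hr", mean_hr, HR_MIN, HR_MAX)
    sd_scale = _validate("sd_scale", sd_scale, 0.0, np.inf)
    lf_power = _validate("lf_power", lf_power, 0.0, np.inf)
    hf_power = _validate("hf_power", hf_power, 0.0, np.inf)
    if not np.isfinite(duration) or duration <= 10.0:
        raise ConfigurationError(f"duration={duration!r} must exceed 10 s")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = 60.0 / mean_hr

    fs_mod = 4.0
    n_mod = int(np.ceil((duration + 2 * m) * fs_mod)) + 8
    mod = np.zeros(n_mod)
    if lf_power > 0:
        mod += _band_limited_noise(n_mod, fs_mod, (0.04, 0.15), lf_power, rng)
    if hf_power > 0:
        mod += _band_limited_noise(n_mod, fs_mod, (0.15, 0.40), hf_power, rng)
    t_mod = np.arange(n_mod) / fs_mod

    times = [0.0]
    t = 0.0
    floor = max(0.25, 0.3 * m)
    while t <= duration:
        rr = m
        if lf_power > 0 or hf_power > 0:
            rr += float(np.interp(t, t_mod, mod))
        if sd_scale > 0:
            rr += sd_scale * rng.standard_normal()
        rr = min(max(rr, floor), 3.0)
        t += rr
        times.append(t)
    return RRSeries.from_beat_times(start_time + np.asarray(times))


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

def _ecg_template(dt: np.ndarray) -> np.ndarray:
    """Biphasic R-dominant wave on +-40 ms support: 1 mV peak at dt=0."""
    w = np.zeros_like(dt)
    m = np.abs(dt) <= _TEMPLATE_HALF_S
    d = dt[m]
    w[m] = (
        1.00 * np.exp(-((d / 0.008) ** 2))
        - 0.22 * np.exp(-(((d - 0.022) / 0.010) ** 2))
        - 0.14 * np.exp(-(((d + 0.022) / 0.010) ** 2))
    )
    return w


def synthesize_ecg(
    rr: RRSeries,
    fs: float = 500.0,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ECGRecord:
    """Place one template beat at each beat time and add white noise.

    Ground-truth beat times are retained in ``record.meta['beat_times']``
    for detector scoring. Rejects beat intervals shorter than the 80 ms
    template support.
    """
    if fs < 250:
        raise ConfigurationError("ECG synthesis requires fs >= 250 Hz")
    if len(rr.intervals) and np.min(rr.intervals) < 2 * _TEMPLATE_HALF_S:
        raise ConfigurationError("beat interval shorter than the template duration")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t0 = rr.beat_times[0]
    duration = rr.beat_times[-1] - t0
    n = int(round(duration * fs)) + 1
    x = np.zeros(n)
    half = int(np.ceil(_TEMPLATE_HALF_S * fs))
    for tb in rr.beat_times:
        c = (tb - t0) * fs
        lo = max(0, int(np.floor(c)) - half)
        hi = min(n, int(np.ceil(c)) + half + 1)
        idx = np.arange(lo, hi)
        x[idx] += _ecg_template(idx / fs - (tb - t0))
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return ECGRecord(
        x, fs, start_time=t0, meta={"beat_times": np.array(rr.beat_times)}
    )


# ---------------------------------------------------------------------------
# GSR synthesis
# ---------------------------------------------------------------------------

def synthesize_gsr(
    tonic_level: float,
    drift_sd: float,
    events: list[tuple[float, float]],
    fs: float = 51.2,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
    duration: float = 180.0,
    tau_rise: float = TAU_RISE_DEFAULT,
    tau_decay: float = TAU_DECAY_DEFAULT,
    tonic_curve: np.ndarray | None = None,
) -> EDARecord:
    """Tonic drift plus stimulus-locked Bateman responses plus white noise.

    ``events`` is a list of (onset_s, amplitude_uS); the unit-peak kernel
    makes each event's true phasic maximum equal its amplitude. The tonic
    drift is Gaussian noise smoothed on a >= 60 s timescale, so the
    tonic/phasic separation is well-posed by construction. Ground-truth
    tonic and phasic traces are retained in ``record.meta``.

    ``tonic_curve`` optionally replaces the constant ``tonic_level`` with an
    arbitrary slow trace of matching length (used for phase-dependent
    levels in cohort simulation).
    """
    if tonic_level <= 0:
        raise ConfigurationError("tonic_level must be positive")
    if drift_sd < 0 or noise_sd < 0:
        raise ConfigurationError("noise scales must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if tonic_curve is not None:
        if len(tonic_curve) != n:
            raise ConfigurationError("tonic_curve length must match duration * fs")
        tonic = np.asarray(tonic_curve, dtype=float).copy()
    else:
        tonic = np.full(n, float(tonic_level))
    if drift_sd > 0:
        drift = gaussian_filter1d(rng.standard_normal(n), sigma=60.0 * fs, mode="reflect")
        drift -= drift.mean()  # drift wanders around the level, never offsets it
        sd = np.std(drift)
        if sd > 0:
            tonic += drift * (drift_sd / sd)
    tonic = np.maximum(tonic, 0.05)

    phasic = np.zeros(n)
    for onset, amp in events:
        if amp < 0:
            raise ConfigurationError(f"negative SCR amplitude {amp}")
        if not 0 <= onset < duration:
            raise ConfigurationError(f"event onset {onset} s outside the record")
        phasic += amp * impulse_response(t - onset, tau_rise, tau_decay)

    x = tonic + phasic
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return EDARecord(
        x, fs, meta={
            "tonic": tonic, "phasic": phasic,
            "events": [(float(o), float(a)) for o, a in events],
        },
    )


# ---------------------------------------------------------------------------
# Subject ground truth and cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SubjectGroundTruth:
    """Generative parameters of one subject at T0 plus T0->T1 effect deltas.

    Per-phase parameters are (Baseline, Task, Recovery) triples. Defaults
    are the cohort-level study conditions; per-subject draws disperse them.
    """

    subject_id: str = "S01"
    mean_hr: tuple[float, float, float] = (75.8, 80.5, 76.5)          # bpm
    sd_scale: tuple[float, float, float] = (0.0255, 0.0191, 0.0191)   # s
    lf_power: float = 4.0e-4                                          # s^2
    hf_power: float = 1.5e-4                                          # s^2
    tonic_level: tuple[float, float, float] = (1.792, 2.819, 2.941)   # uS
    scr_amp_median: float = 0.15                                      # uS, log-normal
    scr_amp_sigma: float = 0.5                                        # log-scale
    deltas: dict[str, tuple | float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hr in self.mean_hr:
            _validate("mean_hr", hr, HR_MIN, HR_MAX)
        for s in self.sd_scale:
            _validate("sd_scale", s, 0.0, np.inf)
        _validate("lf_power", self.lf_power, 0.0, np.inf)
        _validate("hf_power", self.hf_power, 0.0, np.inf)
        for lvl in self.tonic_level:
            if lvl <= 0:
                raise ConfigurationError("tonic_level must be positive")

    def at_session(self, session: str) -> "SubjectGroundTruth":
        """Apply the effect deltas for T1; T0 returns the parameters as-is."""
        if session == "T0" or not self.deltas:
            return self
        kw: dict = {}
        for name, d in self.deltas.items():
            base = getattr(self, name)
            if isinstance(base, tuple):
                d3 = d if isinstance(d, (tuple, list)) else (d,) * 3
                kw[name] = tuple(b + x for b, x in zip(base, d3))
            else:
                kw[name] = base + d
        shifted = replace(self, deltas={}, **kw)
        return shifted

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_hr": [float(v) for v in self.mean_hr],
            "sd_scale": [float(v) for v in self.sd_scale],
            "lf_power": float(self.lf_power),
            "hf_power": float(self.hf_power),
            "tonic_level": [float(v) for v in self.tonic_level],
            "scr_amp_median": float(self.scr_amp_median),
            "scr_amp_sigma": float(self.scr_amp_sigma),
            "deltas": {
                k: ([float(x) for x in v] if isinstance(v, (tuple, list)) else float(v))
                for k, v in self.deltas.items()
            },
        }


#: T0 -> T1 additive effect deltas reproducing the study's direction of
#: change: heart rate and tonic conductance fall, beat-to-beat (vagal)
#: variability and HF power rise.
DEFAULT_EFFECT_DELTAS: dict[str, tuple | float] = {
    "mean_hr": (-6.0, -7.9, -5.0),
    "sd_scale": (0.0113, 0.0071, 0.0049),
    "hf_power": 1.5e-4,
    "lf_power": -1.0e-4,
    "tonic_level": (-1.030, -1.655, -1.662),
}

#: between-subject standard deviations of the T0 parameters
DEFAULT_DISPERSION: dict[str, tuple | float] = {
    "mean_hr": (6.9, 9.0, 7.8),
    "sd_scale": (0.006, 0.005, 0.005),
    "lf_power": 1.5e-4,
    "hf_power": 0.6e-4,
    "tonic_level": (0.8, 1.0, 1.0),
}


@dataclass
class SimulationConfig:
    """Cohort simulation settings; a fixed seed gives byte-identical output."""

    n_subjects: int = 11
    seed: int = 0
    fs_ecg: float = 500.0
    fs_gsr: float = 51.2
    protocol: SessionProtocol = field(default_factory=SessionProtocol)
    dispersion: dict = field(default_factory=lambda: dict(DEFAULT_DISPERSION))
    effect_deltas: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_DELTAS))
    delta_sd_fraction: float = 0.2   # subject-level spread of each delta
    ecg_noise_sd: float = 0.05       # mV
    gsr_noise_sd: float = 0.01       # uS
    gsr_drift_sd: float = 0.05       # uS
    scr_background_rate: float = 1.5 / 60.0   # spontaneous SCRs, events/s

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.fs_ecg < 250 or self.fs_gsr <= 10:
            raise ConfigurationError("sampling rates below synthesis requirements")


@dataclass
class SessionRecording:
    subject_id: str
    session: str  # "T0" | "T1"
    ecg: ECGRecord
    gsr: EDARecord
    protocol: SessionProtocol
    truth: SubjectGroundTruth


def draw_subject(
    cfg: SimulationConfig, subject_id: str, rng: np.random.Generator
) -> SubjectGroundTruth:
    """Draw one subject's T0 parameters and effect deltas from the population."""
    base = SubjectGroundTruth(subject_id=subject_id)

    def _jitter(value, sd):
        if isinstance(value, tuple):
            sd3 = sd if isinstance(sd, (tuple, list)) else (sd,) * 3
            return tuple(v + s * rng.standard_normal() for v, s in zip(value, sd3))
        return value + sd * rng.standard_normal()

    kw: dict = {}
    for name, sd in cfg.dispersion.items():
        kw[name] = _jitter(getattr(base, name), sd)
    # clip to admissible ranges
    kw["mean_hr"] = tuple(np.clip(kw["mean_hr"], 45.0, 180.0))
    kw["sd_scale"] = tuple(np.clip(kw["sd_scale"], 0.005, 0.2))
    kw["lf_power"] = float(np.clip(kw["lf_power"], 1e-5, 5e-3))
    kw["hf_power"] = float(np.clip(kw["hf_power"], 1e-5, 5e-3))
    kw["tonic_level"] = tuple(np.clip(kw["tonic_level"], 0.3, 12.0))

    deltas: dict = {}
    for name, d in cfg.effect_deltas.items():
        if isinstance(d, tuple):
            deltas[name] = tuple(
                x * (1.0 + cfg.delta_sd_fraction * rng.standard_normal()) for x in d
            )
        else:
            deltas[name] = d * (1.0 + cfg.delta_sd_fraction * rng.standard_normal())
    # keep T1 parameters inside bounds
    t1_sd = tuple(
        s + (deltas.get("sd_scale", (0,) * 3)[i] if "sd_scale" in deltas else 0.0)
        for i, s in enumerate(kw["sd_scale"])
    )
    if any(s <= 0.003 for s in t1_sd) :
        deltas.pop("sd_scale", None)
    if "tonic_level" in deltas:
        deltas["tonic_level"] = tuple(
            max(d, 0.2 - lvl) for d, lvl in zip(deltas["tonic_level"], kw["tonic_level"])
        )
    if "hf_power" in deltas and kw["hf_power"] + deltas["hf_power"] <= 1e-6:
        deltas.pop("hf_power")
    if "lf_power" in deltas:
        deltas["lf_power"] = max(deltas["lf_power"], 1e-6 - kw["lf_power"])

    return replace(base, deltas=deltas, **kw)


def _session_rr(
    truth: SubjectGroundTruth, protocol: SessionProtocol, rng: np.random.Generator
) -> RRSeries:
    """Concatenate per-phase RR segments spanning the whole session."""
    spans = protocol.phase_spans()
    times: list[np.ndarray] = []
    t_cursor = 0.0
    for i, phase in enumerate(PHASES):
        t0, t1 = spans[phase]
        seg = simulate_rr_series(
            truth.mean_hr[i],
            truth.sd_scale[i],
            truth.lf_power,
            truth.hf_power,
            duration=t1 - t0,
            seed=rng,
        )
        beats = seg.beat_times + t_cursor
        beats = beats[beats <= t1 + 1e-9]
        if times:
            beats = beats[beats > times[-1][-1] + 0.25]
        times.append(beats)
        t_cursor = beats[-1]
    return RRSeries.from_beat_times(np.concatenate(times))


def _session_gsr_events(
    truth: SubjectGroundTruth, protocol: SessionProtocol, rng: np.random.Generator,
    background_rate: float,
) -> list[tuple[float, float]]:
    events: list[tuple[float, float]] = []
    mu = np.log(truth.scr_amp_median)
    # stimulus-locked responses: onset latency 1-3 s after each stimulus
    for onset in protocol.stimulus_onsets:
        lat = rng.uniform(1.0, 3.0)
        amp = float(np.exp(mu + truth.scr_amp_sigma * rng.standard_normal()))
        events.append((float(onset + lat), amp))
    # sparse spontaneous responses elsewhere
    n_bg = rng.poisson(background_rate * protocol.total_s)
    for _ in range(n_bg):
        t = rng.uniform(0.0, protocol.total_s - 10.0)
        amp = 0.5 * float(np.exp(mu + truth.scr_amp_sigma * rng.standard_normal()))
        events.append((t, amp))
    return sorted(events)


def _tonic_curve(
    truth: SubjectGroundTruth, protocol: SessionProtocol, fs: float
) -> np.ndarray:
    """Per-phase tonic levels joined by 20 s linear ramps at phase boundaries."""
    b, tk, r = truth.tonic_level
    t_end = protocol.total_s
    knots_t = [
        0.0,
        protocol.task_start - 10.0, protocol.task_start + 10.0,
        protocol.task_end - 10.0, protocol.task_end + 10.0,
        t_end,
    ]
    knots_v = [b, b, tk, tk, r, r]
    t = np.arange(int(round(t_end * fs))) / fs
    return np.interp(t, knots_t, knots_v)


def simulate_session(
    truth: SubjectGroundTruth,
    session: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> SessionRecording:
    p = cfg.protocol
    truth_s = truth.at_session(session)
    rr = _session_rr(truth_s, p, rng)
    ecg = synthesize_ecg(rr, fs=cfg.fs_ecg, noise_sd=cfg.ecg_noise_sd, seed=rng)
    events = _session_gsr_events(truth_s, p, rng, cfg.scr_background_rate)
    gsr = synthesize_gsr(
        tonic_level=truth_s.tonic_level[0],
        drift_sd=cfg.gsr_drift_sd,
        events=events,
        fs=cfg.fs_gsr,
        noise_sd=cfg.gsr_noise_sd,
        seed=rng,
        duration=p.total_s,
        tonic_curve=_tonic_curve(truth_s, p, cfg.fs_gsr),
    )
    return SessionRecording(truth.subject_id, session, ecg, gsr, p, truth_s)


def simulate_cohort(cfg: SimulationConfig) -> list[SessionRecording]:
    """Paired (T0, T1) raw sessions for every subject; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    out: list[SessionRecording] = []
    for i in range(cfg.n_subjects):
        truth = draw_subject(cfg, f"S{i + 1:02d}", rng)
        for session in ("T0", "T1"):
            out.append(simulate_session(truth, session, cfg, rng))
    return out
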