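"""Synthetic operating-room sessions with known ground truth.

Every downstream stage (feature extraction, normalization, modelling,
evaluation) is testable without clinical recordings: the generator emits
quasi-periodic ECG with controllable high-frequency RR modulation, a
pulsatile PPG whose per-beat amplitude and area are separately coupled to
a latent nociception trace, EEG as a sum of band-limited noise processes
with trace-coupled per-band power, and multiple noisy expert raters.

The latent trace is a 0-100 score held at a baseline and stepped up at
surgical events (intubation t1, incision t2, extubation t3) with a 30 s
linear rise and an exponential decay (tau = 300 s).  Coupling signs follow
intraoperative physiology: nociceptive activation raises delta and gamma
EEG power and the PPG waveform area, and lowers alpha power, the pulse
amplitude (PPGA), and the parasympathetic RR HF modulation depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import EEG_BANDS, RawSignal, segment_windows

EVENT_LABELS = ("t1", "t2", "t3")

#: default per-rater (bias, sd, start_offset_s, end_offset_s) profiles.
#: Bias range and spread mirror the magnitudes of published inter-rater
#: panels (pairwise difference SDs near 8 imply per-rater sd ~ 8/sqrt(2));
#: the staggered starts/ends exercise the [L, U] synchronizer.
DEFAULT_RATERS = (
    (0.0, 6.0, 0.0, 0.0),
    (-2.0, 6.0, 15.0, 0.0),
    (2.0, 6.0, 0.0, 20.0),
    (5.0, 6.0, 30.0, 10.0),
)

#: baseline EEG band powers (arbitrary uV^2 units) and their fractional
#: coupling to the latent trace (power multiplier 1 + c * trace/100)
EEG_BASE_POWER = {"delta": 30.0, "theta": 10.0, "alpha": 15.0,
                  "beta": 5.0, "gamma": 2.0}
EEG_COUPLING = {"delta": 1.5, "theta": 0.0, "alpha": -0.7,
                "beta": 0.0, "gamma": 1.5}


@dataclass
class SessionSpec:
    """Parameters of one synthetic surgical session."""

    duration_s: float
    events: list = field(default_factory=list)  # [(label, time_s), ...]
    ecg_rate: float = 512.0
    ppg_rate: float = 128.0
    eeg_rate: float = 128.0
    baseline_hr: float = 70.0  # beats/min, typical under general anesthesia
    hf_mod_freq: float = 0.25  # Hz; ventilation at ~15 breaths/min
    hf_amp_ms: float = 40.0    # HF RR modulation depth at trace = 0
    rr_hf_coupling: float = 0.5   # fractional HF-depth drop at trace = 100
    noci_step: float = 15.0    # latent-trace rise per event
    baseline_noci: float = 40.0
    hr_coupling: float = 0.4   # fractional heart-rate rise at trace = 100
    ppga_coupling: float = 0.15    # fractional amplitude drop at trace = 100
    ppg_width_coupling: float = 0.25  # fractional pulse-width rise at trace = 100
    ecg_noise: float = 0.02
    ppg_noise: float = 0.01
    eeg_noise: float = 0.0
    rater_profiles: tuple = DEFAULT_RATERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 128:
            raise ValueError("duration_s must exceed 128 s")
        for label, t in self.events:
            if label not in EVENT_LABELS:
                raise ValueError(f"unknown event label {label!r}")
            if not (64.0 < t < self.duration_s - 64.0):
                raise ValueError(
                    f"event {label} at {t} s outside allowed range "
                    f"(64, {self.duration_s - 64})")
        if not (0.15 <= self.hf_mod_freq <= 0.5):
            raise ValueError("hf_mod_freq must lie in the 0.15-0.5 Hz band")
        if not (40.0 <= self.baseline_hr <= 140.0):
            raise ValueError("baseline_hr must lie in [40, 140] bpm")
        for prof in self.rater_profiles:
            if prof[1] < 0:
                raise ValueError("rater sd must be >= 0")


@dataclass
class NociTrace:
    """Latent nociception trace on a 5 s grid, values in [0, 100]."""

    time_s: np.ndarray
    value: np.ndarray

    def at(self, t) -> np.ndarray:
        """Linear interpolation of the trace at arbitrary times."""
        return np.interp(t, self.time_s, self.value)


@dataclass
class RaterTrace:
    """One expert rater's nociception-assessment time series."""

    rater_id: str
    time_s: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("rater times must be strictly increasing")
        if np.any((self.score < 0) | (self.score > 100)):
            raise ValueError("scores must lie in [0, 100]")


@dataclass
class SessionBundle:
    """Signals, raters, events and ground truth for one synthetic patient."""

    spec: SessionSpec
    ecg: RawSignal
    ppg: RawSignal
    eeg: RawSignal
    raters: list
    events: list
    truth_noci: NociTrace
    ground_truth: dict  # r_times_s, beat_times_s, beat_amplitudes, eeg_band_powers


# ---------------------------------------------------------------------------
# latent trace
# ---------------------------------------------------------------------------

RISE_S = 30.0   # linear rise of the event-response kernel
DECAY_TAU_S = 300.0  # exponential decay time constant


def gen_noci_trace(spec: SessionSpec) -> NociTrace:
    """Baseline plus a smoothed step of height ``noci_step`` per event.

    Each event contributes a kernel rising linearly over 30 s and decaying
    exponentially (tau = 300 s); the sum is clipped to [0, 100].  The trace
    is a deterministic function of the spec (no sampling noise).
    """
    t = np.arange(0.0, spec.duration_s + 1e-9, 5.0)
    v = np.full(t.size, spec.baseline_noci)
    for _, te in spec.events:
        dt = t - te
        k = np.where(dt < 0, 0.0,
                     np.where(dt < RISE_S, dt / RISE_S,
                              np.exp(-(dt - RISE_S) / DECAY_TAU_S)))
        v = v + spec.noci_step * k
    return NociTrace(time_s=t, value=np.clip(v, 0.0, 100.0))


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _r_peak_times(spec: SessionSpec, trace: NociTrace) -> np.ndarray:
    """Beat times with trace-modulated rate and sinusoidal HF modulation.

    Nociceptive activation raises the heart rate (sympathetic tachycardia,
    ``hr_coupling``) and shrinks the parasympathetic HF modulation depth
    (``rr_hf_coupling``).
    """
    times = [0.3]
    while True:
        t = times[-1]
        x_frac = trace.at(t) / 100.0
        base_rr = 60.0 / (spec.baseline_hr * (1.0 + spec.hr_coupling * x_frac))
        depth = (spec.hf_amp_ms / 1000.0) * \
            (1.0 - spec.rr_hf_coupling * x_frac)
        rr = base_rr + depth * np.sin(2 * np.pi * spec.hf_mod_freq * t)
        nxt = t + max(rr, 0.25)
        if nxt >= spec.duration_s - 0.3:
            break
        times.append(nxt)
    return np.asarray(times)


def _add_template(samples: np.ndarray, fs: float, centers: np.ndarray,
                  amps: np.ndarray, shape) -> None:
    """Accumulate a per-beat template ``shape(dt)`` around each center."""
    half = shape.half_width_s
    for tc, a in zip(centers, amps):
        i0 = max(int((tc - half) * fs), 0)
        i1 = min(int((tc + half) * fs) + 1, samples.size)
        tt = np.arange(i0, i1) / fs - tc
        samples[i0:i1] += a * shape(tt)


class _QRSShape:
    """Gaussian-bump QRS-T morphology; only R timing matters downstream."""

    half_width_s = 0.45

    def __call__(self, dt: np.ndarray) -> np.ndarray:
        g = (lambda mu, sig, a: a * np.exp(-0.5 * ((dt - mu) / sig) ** 2))
        return (g(-0.040, 0.010, -0.15) + g(0.0, 0.012, 1.0) +
                g(0.035, 0.010, -0.20) + g(0.250, 0.050, 0.25))


def gen_ecg(spec: SessionSpec, trace: NociTrace,
            rng: np.random.Generator | None = None
            ) -> tuple[RawSignal, np.ndarray]:
    """Synthetic QRS-like ECG at ``ecg_rate`` plus exact R-peak times."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    r_times = _r_peak_times(spec, trace)
    n = int(round(spec.duration_s * spec.ecg_rate))
    x = np.zeros(n)
    _add_template(x, spec.ecg_rate, r_times, np.ones(r_times.size), _QRSShape())
    if spec.ecg_noise > 0:
        x += rng.normal(0.0, spec.ecg_noise, n)
    return RawSignal(kind="ECG", rate=spec.ecg_rate, samples=x), r_times


# ---------------------------------------------------------------------------
# PPG
# ---------------------------------------------------------------------------

class _PulseShape:
    """Gaussian-skewed pulse: fast systolic rise, slower diastolic fall."""

    def __init__(self, width_scale: float):
        # narrow enough that successive pulses stay separated at typical
        # heart rates, so pulse area survives the band-pass DC removal
        self.sl = 0.04 * width_scale
        self.sr = 0.08 * width_scale
        self.half_width_s = 4 * self.sr

    def __call__(self, dt: np.ndarray) -> np.ndarray:
        sig = np.where(dt < 0, self.sl, self.sr)
        return np.exp(-0.5 * (dt / sig) ** 2)


PTT_S = 0.25  # pulse transit time from R peak to peripheral pulse


def gen_ppg(spec: SessionSpec, trace: NociTrace,
            r_times: np.ndarray | None = None,
            rng: np.random.Generator | None = None
            ) -> tuple[RawSignal, np.ndarray, np.ndarray]:
    """Pulsatile PPG synchronous with the heart beat.

    Per-beat amplitude falls with the trace (``ppga_coupling``) while pulse
    width rises (``ppg_width_coupling``), so amplitude and area-under-curve
    move in opposite directions and PPGA / PPG_AUC are separable.

    Returns the signal, the beat times, and the ground-truth amplitudes.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if r_times is None:
        r_times = _r_peak_times(spec, trace)
    beat_times = r_times + PTT_S
    beat_times = beat_times[beat_times < spec.duration_s - 1.0]
    x_frac = trace.at(beat_times) / 100.0
    amps = 1.0 - spec.ppga_coupling * x_frac
    widths = 1.0 + spec.ppg_width_coupling * x_frac

    n = int(round(spec.duration_s * spec.ppg_rate))
    x = np.zeros(n)
    for tc, a, w in zip(beat_times, amps, widths):
        shape = _PulseShape(w)
        half = shape.half_width_s
        i0 = max(int((tc - half) * spec.ppg_rate), 0)
        i1 = min(int((tc + half) * spec.ppg_rate) + 1, n)
        tt = np.arange(i0, i1) / spec.ppg_rate - tc
        x[i0:i1] += a * shape(tt)
    if spec.ppg_noise > 0:
        x += rng.normal(0.0, spec.ppg_noise, n)
    return (RawSignal(kind="PPG", rate=spec.ppg_rate, samples=x),
            beat_times, amps)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def gen_eeg(spec: SessionSpec, trace: NociTrace,
            rng: np.random.Generator | None = None,
            base_power: dict | None = None,
            coupling: dict | None = None
            ) -> tuple[RawSignal, dict, list]:
    """EEG as a sum of five band-limited noise processes.

    Each band is white noise band-passed to its limits, normalized to unit
    variance, and scaled by the square root of its target power
    ``P0 * (1 + c * trace/100)``.  Delta and gamma rise with the trace,
    alpha falls, theta and beta are uncoupled.

    Returns the signal, the ground-truth per-band power per 64 s window,
    and the window grid.
    """
    from scipy import signal as sps

    rng = np.random.default_rng(spec.seed) if rng is None else rng
    base_power = EEG_BASE_POWER if base_power is None else base_power
    coupling = EEG_COUPLING if coupling is None else coupling
    fs = spec.eeg_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    x_frac = trace.at(t) / 100.0
    x = np.zeros(n)
    windows = segment_windows(spec.duration_s)
    gt = {}
    for band, (lo, hi) in EEG_BANDS.items():
        p0 = base_power.get(band, 0.0)
        c = coupling.get(band, 0.0)
        p_t = p0 * (1.0 + c * x_frac)
        if p0 > 0:
            white = rng.normal(0.0, 1.0, n)
            sos = sps.butter(4, [lo, min(hi, fs / 2 * 0.99)],
                             btype="bandpass", fs=fs, output="sos")
            bl = sps.sosfiltfilt(sos, white)
            bl = bl / np.std(bl)
            x += np.sqrt(p_t) * bl
        gt[band] = np.array([
            float(np.mean(p_t[int(s * fs): int(e * fs)]))
            for s, e in windows])
    if spec.eeg_noise > 0:
        x += rng.normal(0.0, spec.eeg_noise, n)
    return RawSignal(kind="EEG", rate=fs, samples=x), gt, windows


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------

def gen_raters(spec: SessionSpec, trace: NociTrace,
               rng: np.random.Generator | None = None) -> list:
    """Noisy expert raters: trace + bias + Gaussian noise, clipped [0, 100].

    Profiles are ``(bias, sd)`` or ``(bias, sd, start_offset_s,
    end_offset_s)``; offsets truncate a rater's span to exercise the
    [L, U] synchronizer.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if not spec.rater_profiles:
        raise ValueError("need at least one rater profile")
    raters = []
    for i, prof in enumerate(spec.rater_profiles):
        bias, sd = prof[0], prof[1]
        off0 = prof[2] if len(prof) > 2 else 0.0
        off1 = prof[3] if len(prof) > 3 else 0.0
        keep = (trace.time_s >= off0) & (trace.time_s <= spec.duration_s - off1)
        tt = trace.time_s[keep]
        score = trace.value[keep] + bias + rng.normal(0.0, sd, tt.size)
        raters.append(RaterTrace(
            rater_id=chr(ord("A") + i), time_s=tt,
            score=np.clip(score, 0.0, 100.0)))
    return raters


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def generate_session(spec: SessionSpec) -> SessionBundle:
    """Generate one complete synthetic session.

    One global seed fans out into independent per-channel substreams so the
    channels can be regenerated independently; the whole bundle is
    bit-identical under an identical spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_ecg, rng_ppg, rng_eeg, rng_rat = (
        np.random.default_rng(s) for s in ss.spawn(4))
    trace = gen_noci_trace(spec)
    ecg, r_times = gen_ecg(spec, trace, rng_ecg)
    ppg, beat_times, beat_amps = gen_ppg(spec, trace, r_times, rng_ppg)
    eeg, eeg_gt, windows = gen_eeg(spec, trace, rng_eeg)
    raters = gen_raters(spec, trace, rng_rat)
    return SessionBundle(
        spec=spec, ecg=ecg, ppg=ppg, eeg=eeg, raters=raters,
        events=list(spec.events), truth_noci=trace,
        ground_truth={
            "r_times_s": r_times,
            "beat_times_s": beat_times,
            "beat_amplitudes": beat_amps,
            "eeg_band_powers": eeg_gt,
            "windows": windows,
        })
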