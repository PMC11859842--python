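"""Feature extraction from raw ECG / PPG / EEG signals.

Raw channels are reduced to eight scalar features per analysis window:
five EEG band powers (delta, theta, alpha, beta, gamma), the spectral
power of the high-frequency RR component (``rrhf_ps``), the smoothed
photoplethysmographic pulse amplitude (``ppga``), and the area under the
rectified PPG waveform (``ppg_auc``).  Windows are 64 s long and advance
in 5 s steps (59 s overlap); power estimates average four non-overlapping
16 s Kaiser-tapered subsegments per window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.interpolate import interp1d

logger = logging.getLogger(__name__)

#: analysis window length (s)
WINDOW_S = 64.0
#: hop between consecutive windows (s)
STEP_S = 5.0
#: length of each power-estimation subsegment (s)
SUBSEG_S = 16.0
#: Kaiser taper shape parameter for subsegment power estimates
KAISER_BETA = 5.0
#: floor for dB conversion of power estimates (dB rel. unit variance)
DB_FLOOR = -120.0
#: high-frequency heart-rate-variability band (Hz)
RRHF_BAND = (0.15, 0.5)
#: uniform resampling rate for the RR tachogram (Hz); the HRV-community
#: convention, and places the HF band inside dyadic wavelet detail bands
TACHO_RATE_HZ = 4.0

#: EEG band limits in Hz
EEG_BANDS = {
    "delta": (0.5, 3.5),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.5, 48.0),
}

#: canonical feature-channel order of the model input
FEATURE_CHANNELS = (
    "delta", "theta", "alpha", "beta", "gamma", "rrhf_ps", "ppga", "ppg_auc",
)


@dataclass
class RawSignal:
    """A uniformly sampled physiological channel."""

    kind: str  # "ECG" | "PPG" | "EEG"
    rate: float  # Hz
    samples: np.ndarray
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN/Inf")
        if self.kind not in ("ECG", "PPG", "EEG"):
            raise ValueError(f"unknown signal kind {self.kind!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.rate


@dataclass
class RRSeries:
    """R-peak times and the successive-difference RR intervals (ms)."""

    r_times_s: np.ndarray
    rr_ms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r_times_s = np.asarray(self.r_times_s, dtype=float)
        if self.r_times_s.size < 2:
            raise ValueError("need at least two R peaks")
        d = np.diff(self.r_times_s)
        if np.any(d <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        self.rr_ms = d * 1000.0


@dataclass
class RRHFSeries:
    """Uniformly sampled high-frequency (0.15-0.5 Hz) RR component, in ms."""

    time_s: np.ndarray
    values: np.ndarray
    rate: float = TACHO_RATE_HZ


@dataclass
class FeatureMatrix:
    """Eight named feature channels on the 64 s-window / 5 s-step grid.

    ``data`` holds one row per window, columns in :data:`FEATURE_CHANNELS`
    order; ``window_end_s`` identifies each window by its end time.
    """

    window_end_s: np.ndarray
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.window_end_s = np.asarray(self.window_end_s, dtype=float)
        missing = set(FEATURE_CHANNELS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing feature channels: {sorted(missing)}")
        # channels are keyed by name: enforce canonical order
        self.data = self.data.loc[:, list(FEATURE_CHANNELS)].reset_index(drop=True)
        if len(self.data) != self.window_end_s.size:
            raise ValueError("window grid and data length mismatch")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def channels(self) -> tuple:
        return FEATURE_CHANNELS

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "window_end_s", self.window_end_s)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        return cls(window_end_s=df["window_end_s"].to_numpy(),
                   data=df.drop(columns=["window_end_s"]))


def segment_windows(duration_s: float) -> list[tuple[float, float]]:
    """Sliding-window grid: ``[k*5, k*5 + 64]`` for all full windows."""
    if duration_s < WINDOW_S:
        warnings.warn("duration shorter than one 64 s window; no windows")
        return []
    n = int(np.floor((duration_s - WINDOW_S) / STEP_S)) + 1
    return [(k * STEP_S, k * STEP_S + WINDOW_S) for k in range(n)]


# ---------------------------------------------------------------------------
# ECG: Pan-Tompkins R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: RawSignal) -> np.ndarray:
    """Detect R-peak times with the Pan-Tompkins algorithm.

    Classical stages: 5-15 Hz band-pass, differentiation, squaring, 150 ms
    moving-window integration, adaptive signal/noise thresholds with
    search-back, and a 200 ms refractory period.  Peak locations are
    refined on a 0.5-40 Hz zero-phase band-passed copy of the ECG.
    """
    if ecg.kind != "ECG":
        raise ValueError("detect_r_peaks expects an ECG signal")
    fs = ecg.rate
    if fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    x = ecg.samples
    if x.size < 5 * fs:
        raise ValueError("ECG must be at least 5 s long")
    if np.ptp(x) < 1e-12:
        warnings.warn("flat ECG signal; no R peaks detected")
        return np.empty(0)

    # display/refinement band-pass
    sos_wide = sps.butter(4, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
    wide = sps.sosfiltfilt(sos_wide, x)
    # detection band-pass (QRS energy band)
    sos_qrs = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos_qrs, x)
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    w = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(sq, np.ones(w) / w, mode="same")

    refractory = int(round(0.2 * fs))
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        warnings.warn("no candidate peaks in integrated ECG")
        return np.empty(0)

    # adaptive signal/noise levels (SPKI / NPKI)
    init = integ[: int(2 * fs)]
    spki = float(np.max(init))
    npki = float(np.mean(init)) * 0.5
    peaks: list[int] = []
    last_accept_i = -1  # index into cand of last accepted peak
    rr_hist: list[float] = []

    def _threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for ci, idx in enumerate(cand):
        p = integ[idx]
        if p > _threshold():
            if peaks:
                rr_hist.append((idx - peaks[-1]) / fs)
                if len(rr_hist) > 8:
                    rr_hist.pop(0)
            peaks.append(idx)
            spki = 0.125 * p + 0.875 * spki
            last_accept_i = ci
        else:
            npki = 0.125 * p + 0.875 * npki
            # search-back: missed beat if the gap exceeds 1.66x the recent RR
            if peaks and rr_hist:
                mean_rr = float(np.mean(rr_hist))
                if (idx - peaks[-1]) / fs > 1.66 * mean_rr:
                    seg = cand[last_accept_i + 1: ci + 1]
                    if seg.size:
                        best = seg[np.argmax(integ[seg])]
                        if integ[best] > 0.5 * _threshold() and best != peaks[-1]:
                            peaks.append(best)
                            spki = 0.25 * integ[best] + 0.75 * spki
                            last_accept_i = ci

    if not peaks:
        warnings.warn("no R peaks above adaptive threshold")
        return np.empty(0)

    # refine to the local maximum of the wide-band ECG, enforce refractory
    half = int(round(0.10 * fs))
    refined = []
    for idx in sorted(peaks):
        lo, hi = max(idx - half, 0), min(idx + half + 1, x.size)
        refined.append(lo + int(np.argmax(wide[lo:hi])))
    refined = np.unique(refined)
    keep = [refined[0]]
    for idx in refined[1:]:
        if idx - keep[-1] >= refractory:
            keep.append(idx)
        elif wide[idx] > wide[keep[-1]]:
            keep[-1] = idx
    return np.asarray(keep) / fs + ecg.start_s


def rr_from_peaks(r_times_s: np.ndarray) -> RRSeries:
    """RR intervals (ms) from successive R-peak times."""
    return RRSeries(r_times_s=np.asarray(r_times_s, dtype=float))


# ---------------------------------------------------------------------------
# RRHF: wavelet band extraction and windowed spectral power
# ---------------------------------------------------------------------------

def extract_rrhf(rr: RRSeries, t_start: float | None = None,
                 t_end: float | None = None) -> RRHFSeries:
    """High-frequency (0.15-0.5 Hz) component of the RR tachogram.

    The unevenly sampled tachogram (each interval stamped at its closing R
    peak) is cubic-interpolated onto a uniform 4 Hz grid with edge-hold
    extrapolation, decomposed with a Daubechies-4 wavelet, and the detail
    levels whose dyadic bands cover 0.15-0.5 Hz (d3: 0.25-0.5 Hz, d4:
    0.125-0.25 Hz at 4 Hz) are reconstructed.  A final zero-phase band-pass
    removes residual out-of-band leakage.
    """
    span = rr.r_times_s[-1] - rr.r_times_s[0]
    if span < WINDOW_S:
        raise ValueError("RR series must span at least 64 s")
    t0 = rr.r_times_s[0] if t_start is None else t_start
    t1 = rr.r_times_s[-1] if t_end is None else t_end
    grid = np.arange(t0, t1 + 1e-9, 1.0 / TACHO_RATE_HZ)
    t_rr = rr.r_times_s[1:]
    f = interp1d(t_rr, rr.rr_ms, kind="cubic", bounds_error=False,
                 fill_value=(rr.rr_ms[0], rr.rr_ms[-1]))
    tach = f(grid)
    tach = tach - np.mean(tach)

    coeffs = pywt.wavedec(tach, "db4", level=4)
    # coeffs = [a4, d4, d3, d2, d1]; keep d3 + d4
    kept = [np.zeros_like(c) for c in coeffs]
    kept[1] = coeffs[1]
    kept[2] = coeffs[2]
    hf = pywt.waverec(kept, "db4")[: grid.size]
    sos = sps.butter(4, RRHF_BAND, btype="bandpass", fs=TACHO_RATE_HZ,
                     output="sos")
    hf = sps.sosfiltfilt(sos, hf)
    return RRHFSeries(time_s=grid, values=hf)


def _tapered_power(seg: np.ndarray, beta: float = KAISER_BETA) -> float:
    """Mean power of a segment estimated through a Kaiser taper."""
    w = np.kaiser(seg.size, beta)
    return float(np.sum((seg * w) ** 2) / np.sum(w ** 2))


def _to_db(p: float) -> float:
    return float(max(10.0 * np.log10(max(p, 0.0) + 1e-300), DB_FLOOR))


def rrhf_power(rrhf: RRHFSeries,
               windows: list[tuple[float, float]]) -> np.ndarray:
    """RRHF spectral power per 64 s window, in dB.

    Each window is split into four non-overlapping 16 s subsegments; the
    Kaiser-tapered power estimates are averaged on the linear scale and
    converted to dB with a floor.  Windows not fully covered by the series
    yield NaN.
    """
    fs = rrhf.rate
    sub_n = int(round(SUBSEG_S * fs))
    out = np.full(len(windows), np.nan)
    t0 = rrhf.time_s[0]
    for i, (s, e) in enumerate(windows):
        i0 = int(round((s - t0) * fs))
        i1 = i0 + 4 * sub_n
        if i0 < 0 or i1 > rrhf.values.size:
            continue
        segs = rrhf.values[i0:i1].reshape(4, sub_n)
        p = float(np.mean([_tapered_power(seg) for seg in segs]))
        out[i] = _to_db(p)
    return out


# ---------------------------------------------------------------------------
# PPG: filtering, AMPD peak detection, PPGA and PPG_AUC
# ---------------------------------------------------------------------------

def filter_ppg(ppg: RawSignal) -> RawSignal:
    """Zero-phase Chebyshev-II fifth-order 0.5-8 Hz band-pass."""
    if ppg.kind != "PPG":
        raise ValueError("filter_ppg expects a PPG signal")
    if ppg.rate < 16:
        raise ValueError("PPG sampling rate must be >= 16 Hz")
    sos = sps.cheby2(5, 30.0, [0.5, 8.0], btype="bandpass", fs=ppg.rate,
                     output="sos")
    y = sps.sosfiltfilt(sos, ppg.samples)
    return RawSignal(kind="PPG", rate=ppg.rate, samples=y, start_s=ppg.start_s)


def detect_ppg_peaks(ppg: RawSignal, max_scale_s: float = 2.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Automatic multiscale-based peak detection (AMPD).

    A point is a scale-``k`` local maximum if it exceeds both neighbours at
    lag ``k``.  The scale with the most local maxima fixes the scalogram
    depth ``lambda``; peaks are the points that are maxima at every scale up
    to ``lambda``.  The maximum scale is capped (default 2 s) to bound work.

    Returns ``(peak_times_s, amplitudes)`` with amplitudes read from the
    input waveform.
    """
    x = ppg.samples
    fs = ppg.rate
    if x.size < 10 * fs:
        raise ValueError("PPG must be at least 10 s long")
    if np.ptp(x) < 1e-12:
        return np.empty(0), np.empty(0)
    xd = sps.detrend(x)
    n = xd.size
    lmax = min(int(max_scale_s * fs), (n - 1) // 2)

    counts = np.empty(lmax, dtype=np.int64)
    for k in range(1, lmax + 1):
        m = (xd[k:n - k] > xd[: n - 2 * k]) & (xd[k:n - k] > xd[2 * k:])
        counts[k - 1] = int(np.count_nonzero(m))
    # the count peaks at half the beat period and (for quasi-periodic
    # signals) near-ties at odd multiples of it; take the smallest scale
    # reaching the plateau so the scalogram depth stays within one period
    lam = int(np.argmax(counts >= 0.95 * counts.max())) + 1

    mask = np.zeros(n, dtype=bool)
    mask[1:-1] = True
    for k in range(1, lam + 1):
        mk = np.zeros(n, dtype=bool)
        mk[k:n - k] = (xd[k:n - k] > xd[: n - 2 * k]) & \
                      (xd[k:n - k] > xd[2 * k:])
        mask &= mk
    idx = np.flatnonzero(mask)
    return idx / fs + ppg.start_s, x[idx]


def compute_ppga(peak_times_s: np.ndarray, amplitudes: np.ndarray,
                 windows: list[tuple[float, float]],
                 gap_warn_s: float = 5.0) -> np.ndarray:
    """Pulse-amplitude trend (PPGA): 16 s moving average of beat amplitudes.

    The per-beat amplitude series is interpolated onto a uniform 4 Hz grid
    (edge-hold at the ends), smoothed with a centred 16 s boxcar, and
    sampled at each window's end time.  Beat gaps longer than ``gap_warn_s``
    are interpolated across and flagged with a warning.
    """
    peak_times_s = np.asarray(peak_times_s, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if peak_times_s.size < 2:
        raise ValueError("need at least two detected beats")
    gaps = np.diff(peak_times_s)
    if np.any(gaps > gap_warn_s):
        warnings.warn(
            f"{int(np.sum(gaps > gap_warn_s))} beat gap(s) > {gap_warn_s} s "
            "interpolated in PPGA")
    t_end = max(windows[-1][1], peak_times_s[-1]) if windows else peak_times_s[-1]
    grid = np.arange(0.0, t_end + 1e-9, 1.0 / TACHO_RATE_HZ)
    amp = np.interp(grid, peak_times_s, amplitudes)
    box = int(round(SUBSEG_S * TACHO_RATE_HZ))
    pad = box // 2
    padded = np.pad(amp, pad, mode="edge")
    smooth = np.convolve(padded, np.ones(box) / box, mode="same")[pad:pad + grid.size]
    return np.interp([e for _, e in windows], grid, smooth)


def compute_ppg_auc(ppg: RawSignal,
                    windows: list[tuple[float, float]]) -> np.ndarray:
    """Trapezoidal integral of the rectified filtered PPG per 64 s window.

    Rectification makes the value invariant to the zero-mean of the
    band-passed waveform.  Partial windows yield NaN.
    """
    fs = ppg.rate
    x = np.abs(ppg.samples)
    out = np.full(len(windows), np.nan)
    for i, (s, e) in enumerate(windows):
        i0 = int(round((s - ppg.start_s) * fs))
        i1 = int(round((e - ppg.start_s) * fs))
        if i0 < 0 or i1 >= x.size + 1:
            continue
        seg = x[i0: min(i1 + 1, x.size)]
        out[i] = np.trapezoid(seg, dx=1.0 / fs)
    return out


# ---------------------------------------------------------------------------
# EEG: band-pass and windowed band powers
# ---------------------------------------------------------------------------

def filter_eeg(eeg: RawSignal) -> RawSignal:
    """Zero-phase 0.5-48 Hz band-pass (Butterworth, order 6)."""
    if eeg.kind != "EEG":
        raise ValueError("filter_eeg expects an EEG signal")
    if eeg.rate < 96:
        raise ValueError("EEG sampling rate must be >= 96 Hz")
    sos = sps.butter(6, [0.5, 48.0], btype="bandpass", fs=eeg.rate,
                     output="sos")
    y = sps.sosfiltfilt(sos, eeg.samples)
    return RawSignal(kind="EEG", rate=eeg.rate, samples=y, start_s=eeg.start_s)


def eeg_band_powers(eeg: RawSignal,
                    windows: list[tuple[float, float]]) -> dict[str, np.ndarray]:
    """Per-band spectral power per 64 s window, in dB.

    Each window is divided into four non-overlapping 16 s subsegments; a
    Kaiser-tapered periodogram of each subsegment is summed over the band
    limits, the four estimates are averaged on the linear scale, and the
    result converted to dB with a floor.
    """
    fs = eeg.rate
    sub_n = int(round(SUBSEG_S * fs))
    out = {b: np.full(len(windows), np.nan) for b in EEG_BANDS}
    x = eeg.samples
    for i, (s, e) in enumerate(windows):
        i0 = int(round((s - eeg.start_s) * fs))
        i1 = i0 + 4 * sub_n
        if i0 < 0 or i1 > x.size:
            continue
        segs = x[i0:i1].reshape(4, sub_n)
        f, pxx = sps.periodogram(segs, fs=fs, window=("kaiser", KAISER_BETA),
                                 axis=-1)
        df = f[1] - f[0]
        for band, (lo, hi) in EEG_BANDS.items():
            sel = (f >= lo) & (f <= hi)
            p = float(np.mean(np.sum(pxx[:, sel], axis=-1) * df))
            out[band][i] = _to_db(p)
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def build_feature_matrix(ecg: RawSignal, ppg: RawSignal,
                         eeg: RawSignal) -> FeatureMatrix:
    """Run the full extraction chain and assemble the 8-channel matrix.

    All three signals must share a common interval of at least 64 s; rows
    with any missing channel are dropped (and the drop count logged).
    """
    starts = {ecg.start_s, ppg.start_s, eeg.start_s}
    t0 = max(ecg.start_s, ppg.start_s, eeg.start_s)
    t1 = min(ecg.start_s + ecg.duration_s, ppg.start_s + ppg.duration_s,
             eeg.start_s + eeg.duration_s)
    if t1 - t0 < WINDOW_S:
        raise ValueError("signals share no common interval of >= 64 s")
    if len(starts) > 1:
        logger.info("signals start at different times; using common span "
                    "[%.1f, %.1f]", t0, t1)
    windows = [(t0 + s, t0 + e) for s, e in segment_windows(t1 - t0)]
    ends = np.array([e for _, e in windows])

    r_times = detect_r_peaks(ecg)
    rr = rr_from_peaks(r_times)
    rrhf = extract_rrhf(rr, t_start=t0, t_end=t1)
    rrhf_ps = rrhf_power(rrhf, windows)

    fppg = filter_ppg(ppg)
    pk_t, pk_a = detect_ppg_peaks(fppg)
    ppga = compute_ppga(pk_t, pk_a, windows)
    ppg_auc = compute_ppg_auc(fppg, windows)

    feeg = filter_eeg(eeg)
    bands = eeg_band_powers(feeg, windows)

    df = pd.DataFrame({**bands, "rrhf_ps": rrhf_ps, "ppga": ppga,
                       "ppg_auc": ppg_auc})
    keep = ~df.isna().any(axis=1)
    if (~keep).any():
        logger.info("dropped %d window(s) with missing channels",
                    int((~keep).sum()))
    return FeatureMatrix(window_end_s=ends[keep.to_numpy()],
                         data=df.loc[keep])
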