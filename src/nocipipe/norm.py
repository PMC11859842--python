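"""Online/offline feature normalization with blended group/individual statistics.

Each feature channel is mapped through a weighted blend of two
transformations: one built from a fixed *group* reference population and
one from the *individual* patient's accumulated intraoperative samples.
The individual weight ``w`` rises linearly from 0 at surgery start to 0.7
after 10 minutes and stays there; the group weight is always ``1 - w``.
Three transformations are supported: empirical-cdf (histogram), z-score,
and min-max.  Offline normalization applies the same formulas with the
individual pool equal to the complete series and ``w`` fixed at 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_CHANNELS, FeatureMatrix

METHODS = ("histogram", "zscore", "minmax")

#: steady-state individual weight
W_MAX = 0.7
#: accumulation horizon before the weight saturates (s)
RAMP_S = 600.0


def weight_schedule(elapsed_s: float) -> float:
    """Individual-data weight: ``0.7 * min(elapsed/600, 1)``.

    Starts at 0 (group transformation weighted 100%), rises linearly until
    10 min of individual data has accumulated, then stays at 0.7.
    """
    if elapsed_s < 0:
        raise ValueError("elapsed time must be non-negative")
    return W_MAX * min(elapsed_s / RAMP_S, 1.0)


# ---------------------------------------------------------------------------
# group reference
# ---------------------------------------------------------------------------

@dataclass
class GroupReference:
    """Per-channel sample pools of the group population.

    Built from the training-split patients only, to keep the test split
    unseen.  Pools back the empirical cdf and supply min/max/mean/std for
    the other two transformations.
    """

    pools: dict = field(default_factory=dict)  # channel -> sorted ndarray

    def __post_init__(self) -> None:
        self.pools = {ch: np.sort(np.asarray(v, dtype=float))
                      for ch, v in self.pools.items()}
        for ch, v in self.pools.items():
            if v.size and np.std(v) == 0:
                raise ValueError(f"group pool for {ch!r} has zero variance")

    @classmethod
    def from_matrices(cls, mats: list) -> "GroupReference":
        pools = {ch: np.concatenate([m.data[ch].to_numpy() for m in mats])
                 for ch in FEATURE_CHANNELS}
        return cls(pools=pools)

    def pool(self, channel: str) -> np.ndarray:
        return self.pools[channel]

    def to_csv(self, path) -> None:
        rows = [(ch, v) for ch, vals in self.pools.items() for v in vals]
        pd.DataFrame(rows, columns=["channel", "value"]).to_csv(path,
                                                                index=False)

    @classmethod
    def from_csv(cls, path) -> "GroupReference":
        df = pd.read_csv(path)
        return cls(pools={ch: g["value"].to_numpy()
                          for ch, g in df.groupby("channel")})


# ---------------------------------------------------------------------------
# the three transformations
# ---------------------------------------------------------------------------

def empirical_cdf(pool: np.ndarray, x) -> np.ndarray:
    """Mid-rank empirical cdf with interpolation between order statistics.

    At a sample point the value is ``(#less + 0.5 * #equal) / n``; between
    distinct order statistics the cdf is linearly interpolated; below the
    pool minimum it is 0 and above the maximum it is 1.
    """
    pool = np.sort(np.asarray(pool, dtype=float))
    n = pool.size
    if n == 0:
        raise ValueError("empty sample pool")
    u, counts = np.unique(pool, return_counts=True)
    less = np.concatenate([[0], np.cumsum(counts)[:-1]])
    f_u = (less + 0.5 * counts) / n
    x = np.asarray(x, dtype=float)
    out = np.interp(x, u, f_u)
    out = np.where(x < u[0], 0.0, out)
    out = np.where(x > u[-1], 1.0, out)
    return out if out.ndim else float(out)


def normalize_histogram(x, w: float, individual: np.ndarray,
                        group: np.ndarray):
    """Blend of individual and group empirical-cdf values, in [0, 1]."""
    individual = np.asarray(individual, dtype=float)
    if individual.size == 0:
        if w > 0:
            warnings.warn("empty individual pool; falling back to group cdf")
        return empirical_cdf(group, x)
    return w * empirical_cdf(individual, x) + (1 - w) * empirical_cdf(group, x)


def normalize_zscore(x, w: float, individual: np.ndarray, group: np.ndarray):
    """Weighted sum of the individual and group z-scores (unbounded)."""
    x = np.asarray(x, dtype=float)
    group = np.asarray(group, dtype=float)
    g_std = np.std(group)
    if g_std <= 0:
        raise ValueError("group pool has zero variance")
    z_group = (x - np.mean(group)) / g_std
    individual = np.asarray(individual, dtype=float)
    i_std = np.std(individual) if individual.size else 0.0
    if i_std > 0:
        z_ind = (x - np.mean(individual)) / i_std
    else:
        if w > 0:
            warnings.warn("individual pool has zero variance; "
                          "individual z-term set to 0")
        z_ind = np.zeros_like(x)
    return w * z_ind + (1 - w) * z_group


def normalize_minmax(x, w: float, individual: np.ndarray, group: np.ndarray):
    """Blend of individual and group min-max maps, clipped to [0, 1]."""
    x = np.asarray(x, dtype=float)
    group = np.asarray(group, dtype=float)
    g_min, g_max = np.min(group), np.max(group)
    if g_max <= g_min:
        raise ValueError("group pool max must exceed min")
    m_group = (x - g_min) / (g_max - g_min)
    individual = np.asarray(individual, dtype=float)
    if individual.size:
        i_min, i_max = np.min(individual), np.max(individual)
    else:
        i_min = i_max = 0.0
    if i_max > i_min:
        m_ind = (x - i_min) / (i_max - i_min)
    else:
        if w > 0:
            warnings.warn("degenerate individual range; "
                          "individual min-max term set to 0.5")
        m_ind = np.full_like(x, 0.5)
    return np.clip(w * m_ind + (1 - w) * m_group, 0.0, 1.0)


_TRANSFORMS = {
    "histogram": normalize_histogram,
    "zscore": normalize_zscore,
    "minmax": normalize_minmax,
}


# ---------------------------------------------------------------------------
# online / offline passes
# ---------------------------------------------------------------------------

@dataclass
class OnlineNormalizerState:
    """Accumulated per-patient samples and the blending-weight state."""

    method: str
    pools: dict = field(default_factory=dict)  # channel -> list of floats
    windows_seen: int = 0
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def normalize_online(features: FeatureMatrix, group: GroupReference,
                     method: str = "minmax",
                     state: OnlineNormalizerState | None = None
                     ) -> FeatureMatrix:
    """Causal pass over a session's feature matrix.

    For each window the current value is first appended to the accumulated
    individual pool (current value inclusive), the weight is taken from the
    elapsed time since surgery start (the window's end time), and the value
    is then transformed.  Guards ensure the output is never NaN, even in
    the first window.
    """
    state = state or OnlineNormalizerState(method=method)
    fn = _TRANSFORMS[state.method]
    t0 = 0.0
    out = {ch: np.empty(len(features)) for ch in FEATURE_CHANNELS}
    raw = features.data
    for i, t_end in enumerate(features.window_end_s):
        elapsed = t_end - t0
        for ch in FEATURE_CHANNELS:
            x = float(raw[ch].iloc[i])
            state.pools.setdefault(ch, []).append(x)
            w = weight_schedule(elapsed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[ch][i] = fn(x, w, np.asarray(state.pools[ch]),
                                group.pool(ch))
        state.windows_seen += 1
        state.weight = weight_schedule(elapsed)
    return FeatureMatrix(window_end_s=features.window_end_s.copy(),
                         data=pd.DataFrame(out))


def normalize_offline(features: FeatureMatrix, group: GroupReference,
                      method: str = "minmax") -> FeatureMatrix:
    """Reference pass: individual pool = complete series, ``w`` = 0.7."""
    fn = _TRANSFORMS[method]
    out = {}
    for ch in FEATURE_CHANNELS:
        series = features.data[ch].to_numpy()
        out[ch] = np.asarray(fn(series, W_MAX, series, group.pool(ch)),
                             dtype=float)
    return FeatureMatrix(window_end_s=features.window_end_s.copy(),
                         data=pd.DataFrame(out))


# ---------------------------------------------------------------------------
# method comparison score
# ---------------------------------------------------------------------------

def score_from_normalized(corr_normalized: float,
                          mae_normalized: float) -> float:
    """Mean of the two rescaled metrics, as a percentage."""
    return (corr_normalized + mae_normalized) / 2.0 * 100.0


def score_methods(pairs: dict) -> dict:
    """Score candidate normalization methods against the offline reference.

    ``pairs`` maps method name to ``(online_series, offline_series)``.
    For each method the Pearson correlation and MAE between the two series
    are computed, min-max rescaled across the candidate methods to [0, 1]
    (MAE inverted so lower error scores higher), and averaged into a
    percentage.  Methods whose series have zero variance are excluded.
    """
    corr, mae = {}, {}
    for name, (online, offline) in pairs.items():
        online = np.ravel(np.asarray(online, dtype=float))
        offline = np.ravel(np.asarray(offline, dtype=float))
        if online.size != offline.size:
            raise ValueError(f"series length mismatch for {name!r}")
        if np.std(online) == 0 or np.std(offline) == 0:
            warnings.warn(f"method {name!r} excluded: zero-variance series "
                          "makes correlation undefined")
            continue
        corr[name] = float(np.corrcoef(online, offline)[0, 1])
        mae[name] = float(np.mean(np.abs(online - offline)))
    if not corr:
        return {}

    def _rescale(vals: dict, invert: bool) -> dict:
        lo, hi = min(vals.values()), max(vals.values())
        if hi == lo:
            return {k: 1.0 for k in vals}
        return {k: ((hi - v) if invert else (v - lo)) / (hi - lo)
                for k, v in vals.items()}

    corr_n = _rescale(corr, invert=False)
    mae_n = _rescale(mae, invert=True)
    return {name: {
        "correlation": corr[name],
        "mae": mae[name],
        "correlation_normalized": corr_n[name],
        "mae_normalized": mae_n[name],
        "score_pct": score_from_normalized(corr_n[name], mae_n[name]),
    } for name in corr}
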