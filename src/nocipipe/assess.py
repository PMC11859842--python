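"""Multi-rater nociception assessments: synchronization, agreement, consensus.

A panel of expert anesthesiologists scores each surgery retrospectively
from the anesthesia record.  Before the scores can serve as a supervised
target they are trimmed to the common interval [L, U] (latest start,
earliest end), screened for outlying raters (one-way ANOVA with a
rater-vs-rest post hoc), checked for reliability (ICC(2,1) absolute
agreement, pairwise Bland-Altman limits of agreement), and averaged into
a consensus trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import RaterTrace

GRID_STEP_S = 5.0
ALPHA = 0.05


@dataclass
class ConsensusNOA:
    """Mean nociception score across retained raters on the common grid."""

    time_s: np.ndarray
    score: np.ndarray
    rater_ids: list = field(default_factory=list)

    def at(self, t) -> np.ndarray:
        """Previous-value (step) interpolation at arbitrary times."""
        idx = np.clip(np.searchsorted(self.time_s, t, side="right") - 1,
                      0, self.time_s.size - 1)
        return self.score[idx]


@dataclass
class AgreementReport:
    """Inter-rater agreement statistics for one panel."""

    anova_f: float | None
    anova_p: float | None
    rater_p: dict          # rater_id -> post-hoc p-value (vs pooled others)
    flagged: list          # rater_ids whose mean differs significantly
    icc: float | None
    icc_ci: tuple | None
    bland_altman: dict     # (id_a, id_b) -> dict(bias, sd, loa, pct_within)


def synchronize(traces: list, step_s: float = GRID_STEP_S
                ) -> tuple[float, float, list]:
    """Trim raters to [L, U] and resample onto one common grid.

    L is the latest start and U the earliest end across raters; samples
    outside [L, U] are discarded and each trace is resampled to a ``step_s``
    grid anchored at L using previous-value interpolation (assessments are
    event-anchored annotations, not continuous measurements).
    """
    if len(traces) < 2:
        raise ValueError("need at least two rater traces")
    starts = [tr.time_s[0] for tr in traces]
    ends = [tr.time_s[-1] for tr in traces]
    lo, up = max(starts), min(ends)
    if up <= lo:
        raise ValueError("disjoint assessments: no common interval")
    grid = np.arange(lo, up + 1e-9, step_s)
    out = []
    for tr in traces:
        idx = np.clip(np.searchsorted(tr.time_s, grid, side="right") - 1,
                      0, tr.time_s.size - 1)
        out.append(RaterTrace(rater_id=tr.rater_id, time_s=grid.copy(),
                              score=tr.score[idx]))
    return lo, up, out


def anova_screen(traces: list, alpha: float = ALPHA
                 ) -> tuple[float | None, float | None, dict, list]:
    """One-way ANOVA across raters with an iterative rater-vs-rest post hoc.

    Returns ``(F, p, per_rater_p, flagged_ids)``.  While the omnibus test
    over the remaining raters is significant, the single most deviant rater
    (smallest Welch p against the pooled others, below ``alpha``) is
    flagged and removed before re-testing — one-at-a-time removal keeps an
    outlier from dragging the pooled reference and implicating the
    consistent raters.  ``per_rater_p`` reports the first-round p-values.
    With fewer than three raters the screen is skipped.
    """
    if len(traces) < 3:
        warnings.warn("fewer than 3 raters; ANOVA screen skipped")
        return None, None, {}, []

    def _posthoc(subset):
        out = {}
        for i, tr in enumerate(subset):
            rest = np.concatenate([s.score for j, s in enumerate(subset)
                                   if j != i])
            _, p_i = stats.ttest_ind(tr.score, rest, equal_var=False)
            out[tr.rater_id] = float(p_i)
        return out

    f_stat, p = stats.f_oneway(*(tr.score for tr in traces))
    rater_p = _posthoc(traces)
    flagged = []
    remaining = list(traces)
    while len(remaining) >= 3:
        _, p_rem = stats.f_oneway(*(tr.score for tr in remaining))
        if not (p_rem < alpha):
            break
        round_p = _posthoc(remaining)
        worst = min(round_p, key=round_p.get)
        if round_p[worst] >= alpha:
            break
        flagged.append(worst)
        remaining = [tr for tr in remaining if tr.rater_id != worst]
    return float(f_stat), float(p), rater_p, flagged


def icc(traces: list) -> tuple[float | None, tuple | None]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Raters are treated as a fixed panel scoring the same time points
    (subjects).  Returns the estimate and its F-based 95% CI, or
    ``(None, None)`` when the between-subject variance vanishes.
    """
    import pingouin as pg

    if len(traces) < 2:
        raise ValueError("ICC needs at least two raters")
    n_pts = traces[0].score.size
    if n_pts < 10:
        raise ValueError("ICC needs at least 10 common time points")
    if any(tr.score.size != n_pts for tr in traces):
        raise ValueError("traces must share a common grid; synchronize first")
    scores = np.column_stack([tr.score for tr in traces])
    if np.allclose(np.var(scores.mean(axis=1)), 0.0):
        warnings.warn("zero between-subject variance: ICC undefined")
        return None, None
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_pts), len(traces)),
        "rater": np.tile([tr.rater_id for tr in traces], n_pts),
        "score": scores.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=long, targets="subject",
                                 raters="rater", ratings="score")
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])  # label differs by version
    row = res.loc[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    return float(row["ICC"]), (float(row[ci_col][0]), float(row[ci_col][1]))


def bland_altman(a: np.ndarray, b: np.ndarray) -> dict:
    """Bland-Altman agreement between two paired series.

    bias = mean(a - b); sd = std(a - b); limits of agreement
    bias +/- 1.96 sd; and the percentage of pairs inside the limits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    within = float(np.mean((d >= loa[0]) & (d <= loa[1])) * 100.0)
    return {"bias": bias, "sd": sd, "loa_low": loa[0], "loa_high": loa[1],
            "pct_within": within}


def consensus(traces: list, keep: list | None = None) -> ConsensusNOA:
    """Pointwise mean over retained raters (all raters by default)."""
    if keep is not None:
        traces = [tr for tr in traces if tr.rater_id in keep]
    if not traces:
        raise ValueError("no raters retained")
    grid = traces[0].time_s
    scores = np.column_stack([tr.score for tr in traces])
    return ConsensusNOA(time_s=grid.copy(), score=scores.mean(axis=1),
                        rater_ids=[tr.rater_id for tr in traces])


def agreement_report(traces: list) -> AgreementReport:
    """Full agreement battery on synchronized traces."""
    f_stat, p, rater_p, flagged = anova_screen(traces)
    icc_val, icc_ci = icc(traces)
    ba = {}
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            ba[(traces[i].rater_id, traces[j].rater_id)] = bland_altman(
                traces[i].score, traces[j].score)
    return AgreementReport(anova_f=f_stat, anova_p=p, rater_p=rater_p,
                           flagged=flagged, icc=icc_val, icc_ci=icc_ci,
                           bland_altman=ba)
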