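"""Evaluation battery and end-to-end pipeline orchestration.

Regression metrics (MAE, Pearson r, MSE, R^2) against the consensus
assessment, before/after analysis of the prediction around the surgical
events t1/t2/t3 (difference of means, standard error, Mann-Whitney U),
and per-patient ROC discrimination of pre- vs post-event samples.

:func:`run_pipeline` wires the whole tool together on synthetic sessions:
simulate -> extract features -> normalize online -> consensus targets ->
train MLP/LSTM -> predict on held-out patients -> evaluate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from . import assess, models, norm, synth
from .features import build_feature_matrix

#: default half-width of the before/after analysis window (s)
SPAN_S = 180.0
#: guard gap excluded around the event instant (s)
GUARD_S = 5.0


def regression_metrics(pred: np.ndarray, target: np.ndarray) -> dict:
    """MAE, Pearson r, MSE and R^2 between aligned series.

    With a zero-variance target, r and R^2 are undefined and reported as
    ``None``.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.size != target.size:
        raise ValueError("pred and target must have equal length")
    err = pred - target
    out = {"mae": float(np.mean(np.abs(err))),
           "mse": float(np.mean(err ** 2))}
    if np.ptp(target) == 0:
        warnings.warn("zero-variance target: r and R^2 undefined")
        out["pearson_r"] = None
        out["r2"] = None
        return out
    ss_tot = float(np.sum((target - np.mean(target)) ** 2))
    out["r2"] = 1.0 - float(np.sum(err ** 2)) / ss_tot
    if np.ptp(pred) == 0:
        warnings.warn("zero-variance prediction: r undefined")
        out["pearson_r"] = None
    else:
        out["pearson_r"] = float(np.corrcoef(pred, target)[0, 1])
    return out


def _split_event(times: np.ndarray, values: np.ndarray, t_event: float,
                 span_s: float, guard_s: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    before = values[(times >= t_event - span_s) & (times < t_event - guard_s)]
    after = values[(times > t_event + guard_s) & (times <= t_event + span_s)]
    return before, after


def event_response(times: np.ndarray, values: np.ndarray, events: list,
                   span_s: float = SPAN_S, guard_s: float = GUARD_S,
                   min_points: int = 5) -> list:
    """Before/after means around each surgical event.

    For each event: mean over ``[t - span, t - guard)`` and
    ``(t + guard, t + span]``, their difference, the standard error of the
    difference, and a two-sided Mann-Whitney U p-value.  Events with fewer
    than ``min_points`` samples on either side are skipped with a warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out = []
    for label, t_event in events:
        before, after = _split_event(times, values, t_event, span_s, guard_s)
        if before.size < min_points or after.size < min_points:
            warnings.warn(f"event {label}: insufficient points "
                          f"({before.size} before / {after.size} after)")
            continue
        diff = float(np.mean(after) - np.mean(before))
        se = float(np.sqrt(np.var(after, ddof=1) / after.size +
                           np.var(before, ddof=1) / before.size))
        if np.ptp(before) == 0 and np.ptp(after) == 0 and \
                np.mean(before) == np.mean(after):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(after, before,
                                         alternative="two-sided").pvalue)
        out.append({"event": label, "time_s": float(t_event),
                    "mean_before": float(np.mean(before)),
                    "mean_after": float(np.mean(after)),
                    "difference": diff, "se": se, "p_value": p})
    return out


def roc_at_events(times: np.ndarray, values: np.ndarray, events: list,
                  span_s: float = SPAN_S, guard_s: float = GUARD_S) -> dict:
    """ROC discrimination of pre- vs post-event samples, pooled per patient.

    Pre-event points are labelled 0 and post-event points 1 across all of
    the patient's events; AUC is the rank statistic (mid-rank ties).
    Returns ``{"auc": ..., "fpr": [...], "tpr": [...]}``; AUC is ``None``
    when only one class is present.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    labels, scores = [], []
    for _, t_event in events:
        before, after = _split_event(times, values, t_event, span_s, guard_s)
        labels.extend([0] * before.size + [1] * after.size)
        scores.extend(before.tolist() + after.tolist())
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUC undefined")
        return {"auc": None, "fpr": [], "tpr": []}
    fpr, tpr, _ = roc_curve(labels, scores)
    return {"auc": float(roc_auc_score(labels, scores)),
            "fpr": fpr.tolist(), "tpr": tpr.tolist()}


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Study conditions for one synthetic multi-patient run."""

    n_train: int = 20
    n_test: int = 5
    duration_s: float = 1800.0
    norm_method: str = "minmax"
    model_kinds: tuple = ("mlp", "lstm")
    span_s: float = SPAN_S
    seed: int = 0
    val_fraction: float = 0.2   # patient-level validation share
    drop_flagged_raters: bool = False
    mlp_overrides: dict = field(default_factory=dict)
    lstm_overrides: dict = field(default_factory=dict)
    out_dir: str | None = None


def _patient_spec(cfg: PipelineConfig, seed: int,
                  rng: np.random.Generator) -> synth.SessionSpec:
    """Per-patient session spec with mild physiological variation."""
    third = cfg.duration_s / 3.0
    events = [("t1", float(rng.uniform(0.4, 0.9) * third)),
              ("t2", float(third + rng.uniform(0.2, 0.8) * third)),
              ("t3", float(2 * third + rng.uniform(0.1, 0.6) * third))]
    return synth.SessionSpec(
        duration_s=cfg.duration_s, events=events,
        baseline_hr=float(rng.uniform(60, 80)),
        baseline_noci=float(rng.uniform(35, 45)),
        hf_mod_freq=float(rng.uniform(0.2, 0.3)),
        seed=seed)


def _prepare_patient(bundle: synth.SessionBundle, group, method: str,
                     drop_flagged: bool) -> dict:
    """Features (online-normalized), consensus target, latent truth."""
    feats = build_feature_matrix(bundle.ecg, bundle.ppg, bundle.eeg)
    feats_n = norm.normalize_online(feats, group, method=method)
    _, _, synced = assess.synchronize(bundle.raters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, _, flagged = assess.anova_screen(synced)
    keep = None
    if drop_flagged and flagged:
        keep = [tr.rater_id for tr in synced if tr.rater_id not in flagged]
    cons = assess.consensus(synced, keep=keep)
    # restrict windows to the raters' common interval, then align targets
    t = feats_n.window_end_s
    sel = (t >= cons.time_s[0]) & (t <= cons.time_s[-1])
    feats_n = _subset(feats_n, sel)
    target = cons.at(feats_n.window_end_s)
    truth = bundle.truth_noci.at(feats_n.window_end_s)
    return {"features": feats_n, "target": target, "truth": truth,
            "events": bundle.events, "flagged": flagged, "raw": feats}


def _subset(fm, mask):
    from .features import FeatureMatrix
    return FeatureMatrix(window_end_s=fm.window_end_s[mask],
                         data=fm.data.loc[mask].reset_index(drop=True))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate, extract, normalize, train, predict and evaluate.

    Returns a JSON-serializable report with per-model training curves,
    per-test-patient regression metrics (vs the consensus assessment and
    vs the latent generating trace), event responses, ROC, and prediction
    variances.  Deterministic under ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_total = cfg.n_train + cfg.n_test
    patient_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(n_total)]

    bundles = [synth.generate_session(_patient_spec(cfg, s, rng))
               for s in patient_seeds]
    train_bundles = bundles[: cfg.n_train]
    test_bundles = bundles[cfg.n_train:]

    # group reference from training-split patients only (no leakage)
    train_raw = [build_feature_matrix(b.ecg, b.ppg, b.eeg)
                 for b in train_bundles]
    group = norm.GroupReference.from_matrices(train_raw)

    train_prep = [_prepare_patient(b, group, cfg.norm_method,
                                   cfg.drop_flagged_raters)
                  for b in train_bundles]
    test_prep = [_prepare_patient(b, group, cfg.norm_method,
                                  cfg.drop_flagged_raters)
                 for b in test_bundles]

    n_val = max(int(round(cfg.val_fraction * cfg.n_train)), 1)
    fit_prep, val_prep = train_prep[:-n_val], train_prep[-n_val:]

    report = {"config": {k: v for k, v in asdict(cfg).items()
                         if k != "out_dir"},
              "models": {}}
    for kind in cfg.model_kinds:
        if kind == "mlp":
            mc = models.ModelConfig.mlp(seed=cfg.seed, **cfg.mlp_overrides)
        else:
            mc = models.ModelConfig.lstm(seed=cfg.seed, **cfg.lstm_overrides)

        def _stack(preps):
            Xs, ys = [], []
            for p in preps:
                X, y, _ = models.make_dataset(p["features"], p["target"],
                                              kind, mc.seq_len)
                Xs.append(X)
                ys.append(y)
            return np.concatenate(Xs), np.concatenate(ys)

        run = models.train(mc, _stack(fit_prep), _stack(val_prep))

        patients = {}
        variances = []
        for i, p in enumerate(test_prep):
            t_pred, y_pred = models.predict(run, p["features"])
            sel = np.isin(p["features"].window_end_s, t_pred)
            target = p["target"][sel]
            truth = p["truth"][sel]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ev = event_response(t_pred, y_pred, p["events"], cfg.span_s)
                roc = roc_at_events(t_pred, y_pred, p["events"], cfg.span_s)
            variances.append(float(np.var(y_pred)))
            patients[f"patient_{i}"] = {
                "regression": regression_metrics(y_pred, target),
                "regression_vs_latent": regression_metrics(y_pred, truth),
                "events": ev,
                "roc": {"auc": roc["auc"]},
                "prediction_variance": variances[-1],
            }
        aucs = [p["roc"]["auc"] for p in patients.values()
                if p["roc"]["auc"] is not None]
        rs = [p["regression_vs_latent"]["pearson_r"]
              for p in patients.values()
              if p["regression_vs_latent"]["pearson_r"] is not None]
        report["models"][kind] = {
            "final_train_loss": run.train_losses[-1],
            "final_val_loss": run.val_losses[-1] if run.val_losses else None,
            "r2_train": run.r2_train,
            "r2_val": run.r2_val,
            "patients": patients,
            "mean_auc": float(np.mean(aucs)) if aucs else None,
            "mean_pearson_vs_latent": float(np.mean(rs)) if rs else None,
            "mean_prediction_variance": float(np.mean(variances)),
        }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
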