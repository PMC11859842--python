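"""MLP and LSTM nociception regressors.

Both models map the normalized 8-channel feature matrix to the 0-100
consensus nociception score (internally scaled to [0, 1]).  The MLP sees
one 8-vector per 64 s window; the LSTM sees sliding sequences of 5
consecutive windows (stride 1) and predicts at the last window.  Default
hyperparameters: MLP hidden 50/30, batch 125, learning rate 1e-3; LSTM
hidden 100/200, batch 256, learning rate 1e-4; both 50 epochs, Adam, MSE
loss, ReLU output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import LSTMNet, MLPNet, train_regressor
from .features import FEATURE_CHANNELS, FeatureMatrix

SEQ_LEN = 5  # LSTM input: 5 consecutive windows
TARGET_SCALE = 100.0


@dataclass
class ModelConfig:
    """Hyperparameters of one regressor."""

    kind: str  # "mlp" | "lstm"
    hidden: tuple
    batch_size: int
    epochs: int = 50
    learning_rate: float = 1e-3
    seq_len: int = SEQ_LEN
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "lstm"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @classmethod
    def mlp(cls, **overrides) -> "ModelConfig":
        base = dict(kind="mlp", hidden=(50, 30), batch_size=125,
                    epochs=50, learning_rate=1e-3)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def lstm(cls, **overrides) -> "ModelConfig":
        base = dict(kind="lstm", hidden=(100, 200), batch_size=256,
                    epochs=50, learning_rate=1e-4, grad_clip=1.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainingRun:
    """A fitted model with its loss history and goodness of fit."""

    config: ModelConfig
    model: object
    channels: tuple
    train_losses: list
    val_losses: list
    r2_train: float
    r2_val: float | None


def make_dataset(features: FeatureMatrix, target: np.ndarray,
                 kind: str, seq_len: int = SEQ_LEN
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Supervised pairs from an aligned feature matrix and target series.

    ``target`` holds one 0-100 score per window (aligned to
    ``features.window_end_s``); it is scaled to [0, 1].  For the MLP each
    window is one sample; for the LSTM, sliding length-``seq_len``
    sequences (stride 1) predict the target at their last window.

    Returns ``(X, y, times)`` where ``times`` stamps each prediction.
    """
    target = np.asarray(target, dtype=float)
    if target.size != len(features):
        raise ValueError(
            f"target length {target.size} != {len(features)} windows")
    gaps = np.diff(features.window_end_s)
    bad = np.flatnonzero(np.abs(gaps - 5.0) > 5.0)
    if bad.size:
        stamps = features.window_end_s[bad][:5]
        raise ValueError(
            f"misaligned window grid around t = {stamps.tolist()} s")
    X = features.values
    y = target / TARGET_SCALE
    t = features.window_end_s
    if kind == "mlp":
        return X, y, t
    if kind == "lstm":
        n = len(features) - seq_len + 1
        if n <= 0:
            raise ValueError("fewer windows than the sequence length")
        idx = np.arange(seq_len)[None, :] + np.arange(n)[:, None]
        return X[idx], y[seq_len - 1:], t[seq_len - 1:]
    raise ValueError(f"unknown model kind {kind!r}")


def train(config: ModelConfig,
          train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray] | None = None
          ) -> TrainingRun:
    """Train a regressor on pre-built supervised pairs.

    Splits must be made by patient (never by window) before calling; the
    run is deterministic under ``config.seed``.
    """
    X, y = train_data
    if X.shape[0] == 0:
        raise ValueError("empty training split")
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_shuffle = (np.random.default_rng(s) for s in ss.spawn(2))
    n_in = X.shape[-1]
    if config.kind == "mlp":
        net = MLPNet(n_in, hidden=config.hidden, rng=rng_init)
    else:
        net = LSTMNet(n_in, hidden=config.hidden, rng=rng_init)
    Xv, yv = (val_data if val_data is not None else (None, None))
    tr_loss, va_loss = train_regressor(
        net, X, y, Xv, yv, epochs=config.epochs,
        batch_size=config.batch_size, lr=config.learning_rate,
        grad_clip=config.grad_clip, rng=rng_shuffle)

    def _r2(yt, yp):
        ss_tot = float(np.sum((yt - np.mean(yt)) ** 2))
        if ss_tot == 0:
            return None
        return 1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot

    r2_train = _r2(y, net.predict(X))
    r2_val = _r2(yv, net.predict(Xv)) if Xv is not None and len(Xv) else None
    return TrainingRun(config=config, model=net, channels=FEATURE_CHANNELS,
                       train_losses=tr_loss, val_losses=va_loss,
                       r2_train=r2_train, r2_val=r2_val)


def save_checkpoint(run: TrainingRun, path) -> None:
    """Persist a fitted model (weights + config) as an ``.npz`` archive."""
    import json

    meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in run.config.__dict__.items()},
            "channels": list(run.channels),
            "r2_train": run.r2_train, "r2_val": run.r2_val,
            "train_losses": run.train_losses, "val_losses": run.val_losses}
    arrays = {f"param_{i}": p for i, p in enumerate(run.model.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainingRun:
    """Restore a fitted model saved with :func:`save_checkpoint`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        params = [data[f"param_{i}"]
                  for i in range(len(data.files) - 1)]
    cfg_d = meta["config"]
    cfg_d["hidden"] = tuple(cfg_d["hidden"])
    config = ModelConfig(**cfg_d)
    n_in = len(meta["channels"])
    if config.kind == "mlp":
        net = MLPNet(n_in, hidden=config.hidden)
    else:
        net = LSTMNet(n_in, hidden=config.hidden)
    for p, saved in zip(net.params, params):
        p[...] = saved
    return TrainingRun(config=config, model=net,
                       channels=tuple(meta["channels"]),
                       train_losses=meta["train_losses"],
                       val_losses=meta["val_losses"],
                       r2_train=meta["r2_train"], r2_val=meta["r2_val"])


def predict(run: TrainingRun, features: FeatureMatrix
            ) -> tuple[np.ndarray, np.ndarray]:
    """Nociception trace (0-100) from a fitted model.

    One prediction per window (MLP) or per complete sequence (LSTM, so the
    first prediction lags by ``(seq_len - 1) * 5`` s); outputs are rescaled
    by 100 and clipped to [0, 100].
    """
    if tuple(features.channels) != tuple(run.channels):
        raise ValueError(
            f"feature channels {features.channels} do not match the "
            f"channels the model was trained on ({run.channels})")
    X = features.values
    t = features.window_end_s
    if run.config.kind == "lstm":
        seq = run.config.seq_len
        n = X.shape[0] - seq + 1
        if n <= 0:
            raise ValueError("fewer windows than the sequence length")
        idx = np.arange(seq)[None, :] + np.arange(n)[:, None]
        X = X[idx]
        t = t[seq - 1:]
    y = run.model.predict(X) * TARGET_SCALE
    return t, np.clip(y, 0.0, 100.0)
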