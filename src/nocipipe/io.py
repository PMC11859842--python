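"""Plain-text I/O for signals, raters, events and feature matrices.

Signals travel as columnar CSV with a one-line metadata header comment
(``# nocipipe-signal kind=ECG rate=512.0 start_s=0.0``) followed by a
single ``value`` column; EDF files are read through ``mne`` when it is
installed.  Raters are ``time_s,score`` CSV, events ``label,time_s``,
and the latent truth ``time_s,noci``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import RawSignal
from .synth import RaterTrace, SessionBundle

_MAGIC = "# nocipipe-signal"


def write_signal_csv(sig: RawSignal, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC} kind={sig.kind} rate={sig.rate} "
                 f"start_s={sig.start_s}\n")
        fh.write("value\n")
        np.savetxt(fh, sig.samples, fmt="%.6g")


def read_signal_csv(path) -> RawSignal:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith(_MAGIC):
            raise ValueError(f"{path} is not a nocipipe signal CSV")
        meta = dict(tok.split("=") for tok in header.split()[2:])
        samples = np.loadtxt(fh, skiprows=1)
    return RawSignal(kind=meta["kind"], rate=float(meta["rate"]),
                     samples=samples, start_s=float(meta["start_s"]))


def read_signal(path, kind: str | None = None,
                channel: str | None = None) -> RawSignal:
    """Read a signal from CSV or (if ``mne`` is available) EDF."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        name = channel or raw.ch_names[0]
        data = raw.get_data(picks=[name])[0]
        return RawSignal(kind=kind or "EEG", rate=float(raw.info["sfreq"]),
                         samples=data)
    return read_signal_csv(path)


def write_raters_csv(raters: list, out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in raters:
        p = out_dir / f"rater_{tr.rater_id}.csv"
        pd.DataFrame({"time_s": tr.time_s, "score": tr.score}).to_csv(
            p, index=False)
        paths.append(p)
    return paths


def read_rater_csv(path, rater_id: str | None = None) -> RaterTrace:
    df = pd.read_csv(path)
    rid = rater_id or Path(path).stem.replace("rater_", "")
    return RaterTrace(rater_id=rid, time_s=df["time_s"].to_numpy(),
                      score=df["score"].to_numpy())


def write_events_csv(events: list, path) -> None:
    pd.DataFrame(events, columns=["label", "time_s"]).to_csv(path,
                                                             index=False)


def read_events_csv(path) -> list:
    df = pd.read_csv(path)
    return [(str(r.label), float(r.time_s)) for r in df.itertuples()]


def write_session(bundle: SessionBundle, out_dir) -> None:
    """Write one synthetic session (signals, raters, events, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_signal_csv(bundle.ecg, out_dir / "ecg.csv")
    write_signal_csv(bundle.ppg, out_dir / "ppg.csv")
    write_signal_csv(bundle.eeg, out_dir / "eeg.csv")
    write_raters_csv(bundle.raters, out_dir / "raters")
    write_events_csv(bundle.events, out_dir / "events.csv")
    pd.DataFrame({"time_s": bundle.truth_noci.time_s,
                  "noci": bundle.truth_noci.value}).to_csv(
        out_dir / "truth.csv", index=False)
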