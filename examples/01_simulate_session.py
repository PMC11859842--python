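"""Generate one synthetic operating-room session and inspect its ground truth.

A session bundles ECG/PPG/EEG at their native rates, a panel of noisy
expert raters, the three surgical events, and the latent nociception trace
every other stage is tested against.
"""

import numpy as np

from nocipipe import SessionSpec, generate_session

spec = SessionSpec(
    duration_s=900.0,
    events=[("t1", 200.0), ("t2", 450.0), ("t3", 700.0)],
    seed=42,
)
bundle = generate_session(spec)

tr = bundle.truth_noci
print(f"latent trace: {tr.value.min():.1f}-{tr.value.max():.1f} "
      f"on a {tr.time_s[1] - tr.time_s[0]:.0f} s grid")
for label, t in bundle.events:
    before = tr.value[(tr.time_s >= t - 180) & (tr.time_s < t)].mean()
    after = tr.value[(tr.time_s > t) & (tr.time_s <= t + 180)].mean()
    print(f"  {label} at {t:.0f} s: trace mean {before:.1f} -> {after:.1f}")

r = bundle.ground_truth["r_times_s"]
print(f"ECG: {bundle.ecg.samples.size} samples at {bundle.ecg.rate:.0f} Hz, "
      f"{r.size} R peaks (mean HR {60 / np.mean(np.diff(r)):.0f} bpm)")
print(f"raters: {[tr.rater_id for tr in bundle.raters]} "
      f"(spans staggered to exercise synchronization)")

# The trace mean rises after each event: that is the signal the feature
# extraction and the regressors must recover from the raw waveforms.
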