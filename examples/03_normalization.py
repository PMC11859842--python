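"""Compare online normalization methods against the offline reference.

Online normalization blends a fixed group reference with the patient's
accumulated samples; the individual weight ramps from 0 to 0.7 over the
first 10 minutes.  The offline reference fixes the weight at 0.7 with the
complete series as the individual pool.  Methods are scored by how closely
the online pass reproduces the offline one.
"""

import warnings

import numpy as np

from nocipipe import (GroupReference, SessionSpec, build_feature_matrix,
                      generate_session, normalize_offline, normalize_online,
                      score_methods, weight_schedule)

print("individual weight: w(0 s) =", weight_schedule(0.0),
      " w(300 s) =", weight_schedule(300.0),
      " w(600 s) =", weight_schedule(600.0))

# group reference from three "training" patients
train = [generate_session(SessionSpec(
    duration_s=900.0, events=[("t1", 300.0), ("t2", 600.0)], seed=s))
    for s in (10, 11, 12)]
group = GroupReference.from_matrices(
    [build_feature_matrix(b.ecg, b.ppg, b.eeg) for b in train])

# one new patient, normalized online and offline
b = generate_session(SessionSpec(
    duration_s=900.0, events=[("t1", 300.0), ("t2", 600.0)], seed=20))
fm = build_feature_matrix(b.ecg, b.ppg, b.eeg)

pairs = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for method in ("histogram", "zscore", "minmax"):
        online = normalize_online(fm, group, method=method)
        offline = normalize_offline(fm, group, method=method)
        pairs[method] = (online.data["ppga"].to_numpy(),
                         offline.data["ppga"].to_numpy())

print("\nonline vs offline on the PPGA channel:")
for method, res in score_methods(pairs).items():
    print(f"  {method:9s} corr {res['correlation']:+.3f}  "
          f"MAE {res['mae']:.3f}  score {res['score_pct']:.0f}%")

# The score averages the rescaled correlation and (inverted) MAE across
# methods; the method that best reproduces the offline reference wins.
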