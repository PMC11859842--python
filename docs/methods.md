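# Methods

`nocipipe` estimates intraoperative nociception (the physiological response
to noxious stimuli under general anesthesia, as opposed to conscious pain)
from three simultaneously recorded signals: single-lead ECG (512 Hz),
photoplethysmography (128 Hz) and single-channel EEG (128 Hz).  The target
is the nociception assessment (NOA), a 0–100 score assigned retrospectively
by expert anesthesiologists from the anesthesia record.  This note records
the model, the processing choices, and what the synthetic test bed does and
does not establish.

## Signal features

All channels are reduced to eight features on a sliding-window grid:
**64 s windows advancing in 5 s steps** (59 s overlap), each window
identified by its end time.  Power-type features divide the window into
**four non-overlapping 16 s subsegments**, estimate power per subsegment
through a Kaiser taper, average on the linear scale, and convert to dB
(floor −120 dB relative to unit variance; the floor keeps silent windows
finite).

- **R peaks** are detected with the Pan–Tompkins stages: 5–15 Hz band-pass,
  differentiation, squaring, 150 ms moving integration, adaptive
  signal/noise thresholds with search-back, 200 ms refractory period.
  Peak positions are refined on a 0.5–40 Hz zero-phase filtered copy.
- **RRHF** — the 0.15–0.5 Hz (parasympathetic) component of the RR series —
  is obtained by cubic-resampling the tachogram to a uniform 4 Hz grid
  (the HRV-community convention; it puts the HF band inside dyadic wavelet
  bands), reconstructing Daubechies-4 detail levels d3 + d4 (0.25–0.5 and
  0.125–0.25 Hz at 4 Hz), and removing residual leakage with a final
  0.15–0.5 Hz zero-phase band-pass.  The tachogram is extended to the full
  session span by edge-hold so the first analysis window is covered;
  without that extension the first window could never satisfy the
  "first window ends at 64 s" grid contract.  **RRHF_PS** is the windowed
  Kaiser-tapered power of this series in dB.
- **PPG** is band-passed with a zero-phase Chebyshev-II fifth-order
  0.5–8 Hz filter (30 dB stopband).  Beats are found with AMPD (automatic
  multiscale-based peak detection): a point is a scale-*k* maximum when it
  exceeds both neighbours at lag *k*; the scale with the most maxima fixes
  the scalogram depth λ and peaks are maxima at every scale ≤ λ.  Two
  implementation details matter: the maximum scale is capped at 2 s to
  bound work, and λ is taken as the *smallest* scale reaching the count
  plateau, because for quasi-periodic signals the count near-ties at odd
  multiples of the half period and choosing a multi-period scale collapses
  detection onto envelope maxima.
- **PPGA** is the per-beat amplitude series smoothed with a centred 16 s
  moving average on a uniform 4 Hz grid (edge-hold), sampled at window
  ends.  Beat gaps over 5 s are interpolated and flagged.
- **PPG_AUC** is the trapezoidal integral of the rectified filtered PPG per
  window; rectification makes the value invariant to the zero mean the
  band-pass imposes.
- **EEG** is band-passed 0.5–48 Hz (Butterworth order 6, zero-phase; the
  order is chosen so a 60 Hz tone is attenuated ≥ 20 dB at 128 Hz
  sampling). Band powers use the limits delta 0.5–3.5, theta 4–7.5,
  alpha 8–12, beta 13–30, gamma 30.5–48 Hz, summed from Kaiser-tapered
  (β = 5, a near-Hamming sidelobe compromise) subsegment periodograms —
  linear-scale averaging before the dB conversion.

Windows missing any channel are dropped, not imputed.  All filters run
zero-phase (`sosfiltfilt`), so features carry no group delay relative to
the window grid.

## Normalization

Inter- and intra-patient variability is handled by blending two
transformations per channel: one built from a fixed **group** reference
pool and one from the patient's **accumulated** intraoperative samples.
The individual weight follows `w(t) = 0.7 · min(t/600 s, 1)` — group-only
at induction, linear hand-over during the first 10 minutes, then fixed at
0.7 individual / 0.3 group.  Three maps are provided:

- *histogram*: `w·F_ind(x) + (1−w)·F_group(x)` with mid-rank empirical
  cdfs, linearly interpolated between order statistics, clamped to [0, 1];
- *z-score*: `w·z_ind(x) + (1−w)·z_group(x)` (unbounded);
- *min–max*: the same blend of min–max maps, clipped to [0, 1] because the
  regressors are trained on bounded inputs.

The accumulated pool is updated with the current value *before* it is
normalized (current-value inclusive), so the first window is always
defined: degenerate guards return the group term alone (histogram), a zero
individual z-term, or 0.5 for a zero-width min–max range.  Offline
normalization uses the complete series as the individual pool with `w`
fixed at 0.7; the online pass provably converges to it as the pool fills.
Methods are compared by the score `(corr_norm + MAE_norm)/2`, where the
Pearson correlation and MAE between online and offline series are min–max
rescaled across the candidate methods (MAE inverted).  The group reference
is always built from training-split patients only, to avoid leakage into
held-out evaluations.

## Rater handling

Raters are synchronized to `[L, U]` (latest start, earliest end;
disjoint spans are an error) and resampled to a 5 s grid by previous-value
interpolation, since assessments are event-anchored annotations rather
than continuous measurements.  A one-way ANOVA with an *iterative*
rater-vs-rest Welch post hoc (α = 0.05) flags outlying raters one at a
time, re-testing after each removal — a single large outlier would
otherwise drag the pooled reference and implicate the consistent raters.
Flagged raters are only excluded when explicitly requested, preserving
auditability.  Reliability
is quantified with ICC(2,1) — two-way random effects, absolute agreement,
single rater, computed via pingouin — chosen because the raters form a
fixed panel scoring the same time points, and with pairwise Bland–Altman
bias, SD and 1.96·SD limits of agreement.  The supervised target is the
pointwise mean of the retained raters.

## Models

Two regressors map the normalized 8-vector to the consensus score scaled
to [0, 1] (the 0–100 scale is restored and clipped at prediction time):

| | hidden | batch | epochs | learning rate | optimizer | output |
|---|---|---|---|---|---|---|
| MLP | 50 / 30 (ReLU) | 125 | 50 | 1e-3 | Adam | ReLU |
| LSTM | 100 / 200 (sigmoid gates) | 256 | 50 | 1e-4 | Adam | ReLU |

The MLP consumes one window per sample; the LSTM consumes sliding
sequences of 5 consecutive windows (stride 1, stateless across batches)
and predicts at the last window, so its first prediction lags an extra
4 × 5 s.  Both are implemented directly in NumPy (manual backpropagation,
BPTT for the LSTM) with seeded initialization and shuffling, which makes
training bit-reproducible; gradients are verified against central
differences in the test suite.  The LSTM clips gradients at global norm
1.0 to guard against unstable updates.  Splits are always by patient,
never by window.  Target scaling to [0, 1] is an inference from the loss
magnitudes such a model produces, not an externally fixed convention.

## Evaluation

Predictions are scored with MAE, Pearson r, MSE and R²; around each
surgical event (intubation t1, incision t2, extubation t3) the mean over
`[t−180 s, t−5 s)` is compared with `(t+5 s, t+180 s]` (difference of
means, standard error, two-sided Mann–Whitney U).  The 5 s guard gap
excludes the transition window itself; the 180 s span is a configuration
default, exposed because no canonical value exists.  ROC analysis labels
pre-event samples 0 and post-event samples 1, pooled within a patient,
with AUC as the mid-rank statistic; per-patient AUCs are summarized by
their mean.  F1/precision/recall are deliberately out of scope.

## Synthetic sessions

Because no public clinical recordings exist for this task, the package
ships a generator whose ground truth feeds every oracle:

- a latent nociception trace (0–100) at 5 s cadence: baseline (default 40)
  plus, per event, a kernel rising linearly over 30 s and decaying
  exponentially with τ = 300 s (step height default 15 — consistent with
  before/after means in the 40s-to-low-60s range);
- ECG as a Gaussian-bump QRS-T template at exact R times; RR intervals
  carry sinusoidal HF modulation (default 0.25 Hz ≈ ventilation at 15
  breaths/min, depth 40 ms) whose depth *falls* with the trace
  (parasympathetic withdrawal) while heart rate *rises* with it
  (sympathetic tachycardia, +40 % at trace 100);
- PPG as a skewed-Gaussian pulse train synchronous with the beat (0.25 s
  transit delay): per-beat amplitude falls with the trace (−15 % at 100)
  while pulse width rises (+25 %), so amplitude and area decouple; the
  windowed PPG_AUC feature rises with the trace mainly through the beat
  count.  The pulse is kept narrow (σ ≈ 40/80 ms rise/fall) because pulse
  overlap would otherwise push the waveform toward DC, which the band-pass
  removes;
- EEG as five unit-variance band-limited noise processes scaled by
  √(P₀(1 + c·trace/100)) with baseline powers 30/10/15/5/2 (arbitrary
  units) and couplings delta +1.5, alpha −0.7, gamma +1.5, theta/beta 0 —
  delta/gamma arousal and alpha dropout under noxious stimulation;
- raters as trace + bias + Gaussian noise clipped to [0, 100].  Default
  panel: biases 0/−2/+2/+5, sd 6 (pairwise difference SDs ≈ 6√2 ≈ 8.5,
  the magnitude published inter-rater panels show), with staggered
  starts/ends up to 30 s to exercise the synchronizer.

One seed fans out into per-channel substreams, so a bundle is
bit-identical under the same spec and channels can be regenerated
independently.  The trace itself is deterministic (no sampling noise): an
event-free spec yields a constant baseline.

**What the generator does not emulate:** pharmacokinetics, arrhythmia,
motion or electrocautery artifacts, multi-lead/multi-channel montages,
drifting electrode quality, or any correlation structure between raters
beyond shared truth.  Passing tests therefore demonstrate that the
pipeline recovers known couplings from clean quasi-physiological signals —
not clinical performance.

## Study conditions for the recovery experiment

The end-to-end experiment uses 25 synthetic patients (20 training, of
which the last 4 form the validation split, and 5 held out), 30 min each,
with per-patient variation in baseline heart rate (60–80 bpm), baseline
nociception (35–45), HF frequency (0.2–0.3 Hz) and jittered event times.
Min–max is the default normalization.  Acceptance checks assert the MLP's
mean Pearson correlation against the latent trace (≥ 0.7), its mean
event AUC (≥ 0.8), and that the LSTM's prediction variance does not
exceed the MLP's (the "smoother predictions" property stated as a
testable inequality).  These sizes keep a full run in the minutes range
on a single CPU.  The correlation and AUC statements are stable across
seeds with wide margin; the variance inequality is the marginal one —
after 50 epochs both models reach similar reactivity on this generator,
so the LSTM's smoothness advantage is small and can invert under an
unlucky seed.

## Numerical conventions and edge cases

- Half-open `[start, end)` 0-based sample indexing; windows keyed by end
  time; the PPG_AUC trapezoid includes the closing sample.
- Degenerate inputs are warnings plus guarded values (flat ECG → empty
  peak list; empty pools → group-only; zero-width ranges → 0.5), never
  NaN in a normalized matrix.
- Zero-variance targets make r/R² undefined and are reported as null, not
  silently zeroed.
- Mann–Whitney p-values use SciPy's exact method whenever sample sizes
  permit, matching exhaustive permutation enumeration on small instances.

## Known limitations

- The MLP/LSTM training loop is single-threaded NumPy; it is sized for
  the feature-rate data volumes of this problem (hundreds of windows per
  patient), not for raw-signal-rate learning.
- AMPD's plateau heuristic assumes a quasi-periodic pulse; it is not a
  general-purpose peak picker for arrhythmic PPG.
- The RRHF edge-hold extrapolation slightly biases the first and last
  windows of a session toward their nearest observed RR values.
- ICC confidence intervals are F-based and assume balanced complete data.
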