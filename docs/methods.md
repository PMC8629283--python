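# Methods

## Scope

punchlab is a synthetic, desk-scale reconstruction of a three-series study
design: (1) build an "optimal punch" dataset and classifier from an elite
cohort, (2) test whether conformance to that model predicts punch quality in
a weaker cohort, (3) simulate a month of LED-biofeedback training against a
control arm. Everything runs from seeds on one CPU; no sensor hardware, no
human data.

## Punch statistics

For a punch with peak pad force F (N), rise time t (s, onset of force
increase to force maximum) and fist speed at impact v (m/s):

- effective force `F_eff = F / t` — a power proxy: the same force delivered
  over a shorter rise is a more effective punch;
- punch quality `q_p = F_eff · v` — the scalar used to rank punches;
- relative quality `q_rp = q_p / max(q_p)` — normalized within a boxer's
  series (so boxers of different absolute strength are comparable), while
  best-punch *labeling* is applied to the pooled per-hand data: the top
  `max(1, floor(0.05·N))` by `q_p`, ties broken by punch id.

All computation is done in full precision; rounding to 2 decimals happens
only for display and table comparison.

## Synthetic signal model

The generator is the package's definition of the study conditions, not a
fitted model of real punches.

**Parameter draws.** A boxer's skill u ∈ [0,1] maps linearly to a force
scale in [897, 1280] N, a rise-time base in [0.400, 0.152] s (decreasing)
and a speed base in [6.85, 11.50] m/s; a ±0.15 smear around skill
individualizes boxers. Per punch, a shared *effort* factor (bounded uniform,
sd = `jitter_sd`) multiplies force and speed and divides rise time, with
independent residual jitters of half that sd on each; elite boxers are more
consistent (`jitter_sd` = 0.02 + 0.08·(1 − skill)). The effort factor is
what makes the best-punch class learnable from the IMU alone: a harder
punch is also a faster one with larger wrist signals. These ranges are
budgeted so that every elite draw, after the left-hand asymmetry (×0.97)
and worst-case jitter, stays inside the published elite envelopes
(F 790.22–1402.26 N, t 0.138–0.984 s, v 6.03–14.32 m/s). The speed ceiling
of 11.5 m/s is a physical constraint of the signal model: under the window
convention below, a 14 m/s punch with a 0.14 s rise would require a
punch-axis pulse above the accelerometer's ±16 g range.

**Force curve.** Rise times and onsets are quantized to the 500 Hz sample
grid so the force maximum falls exactly on a sample. The normalized rise is
piecewise: a near-instant jump to 45 % of peak (threshold detectors then
date the onset at the onset sample itself), a slow ramp that crosses the
half-peak *impact* threshold exactly at 95 % of the rise time, a fast final
ramp to the peak, then exponential decay (30 ms time constant). The impact
instant is defined as the half-peak crossing on the rising edge — the study
convention "pressure changed to a certain value" made concrete.

**IMU channels.** The punch-axis acceleration (accelerometer Y) is a
half-sine spanning onset→impact whose amplitude is calibrated so that the
*trapezoidal integral over the sampled window* equals the true impact speed
— the same quadrature the analysis side uses, so zero-noise recovery is
exact by construction rather than approximate. The other five channels are
Gaussian pulses (per-boxer template amplitudes, widths and phases relative
to impact) scaled with punch speed. Additive white Gaussian sensor noise
(defaults 0.05 g, 5 deg/s, 0.5 % of peak force) is applied last; any
saturation beyond ±16 g / ±2000 deg/s is clipped and flagged in the ground
truth, never silent.

**What the generator does not emulate:** multi-joint kinematics, gravity
components, hook/uppercut waveforms, fatigue, inter-punch correlation.
Passing tests therefore demonstrate the pipeline's correctness and internal
consistency, not field accuracy on real boxers.

## Signal processing

- **Kalman smoothing**: an independent 1-state random-walk filter per
  channel, initialized from the first sample with a large prior variance.
  The closed-form steady-state gain is exposed for testing; the filter is
  linear with unit DC gain, hence commutes with constant offsets.
- **Detection**: excursions of the 5-sample-smoothed force above
  `onset_frac` (default 0.05) of the curve maximum; fragments closer than
  40 ms are merged, runs shorter than 3 samples are dropped, and an
  excursion must reach 25 % of the curve maximum to count (a 5σ noise spike
  can otherwise clear a lower bar on long streams). Within an excursion,
  the peak is the raw argmax, the onset the last sub-threshold sample
  before it, the impact the first sample at or above `impact_frac`
  (default 0.5) of the local peak.
- **Impact speed**: trapezoidal integral of the punch-axis acceleration
  (g → m/s², 1 g = 9.80665) over [onset, impact], absolute value.
- **Classifier window**: the last 100 samples per channel up to and
  including the impact sample, concatenated channel-major
  (ax, ay, az, gx, gy, gz) — 600 raw, unnormalized sensor values. Windows
  that would start before the segment are edge-padded and logged.

## Classifier

The architecture is fixed by the study: 600–512–256–128–64–2 with a sigmoid
on every layer, two one-hot output nodes (node 1 = best punch), per-node
binary cross-entropy, Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), batch 32,
50 epochs by default, seeded Glorot-uniform initialization. It is
implemented directly on NumPy. Numerical choices of ours:

- inputs are standardized per feature inside `train` (statistics stored
  with the model): raw gyro values of order 100 saturate an all-sigmoid
  stack at initialization; the stored windows themselves stay raw;
- class imbalance (5 % positives) is countered by sample weights inversely
  proportional to class frequency;
- precision/recall conventions: PR (RC) is 0 when its denominator is 0 and
  F1 is 0 when PR + RC = 0, with a logged warning;
- the conformance score normalizes the two sigmoid outputs against each
  other, `s_best / (s_best + s_not_best)` (0.5 if both vanish); the raw
  two-node outputs remain available through `predict_proba`.

Cross-validation follows the study protocol literally: shuffle once
(seeded), split into k = 10 groups (scikit-learn's KFold does the split),
train a freshly initialized model on each complement, record test loss and
accuracy per fold.

## Feedback and learning simulation

LED quantization uses five equal score bins (edges 0.2/0.4/0.6/0.8); score
1.0 → 5 LEDs, 0.0 → 1 LED. Each simulated boxer carries a latent technique
level u that drifts toward optimal by multiplicative shrinkage of the gap:
per punch, `u += (rate/punches_per_session) · m · (1 − u)` with
`m = 1 + (feedback_gain − 1)·(leds/5)` when feedback is on and `m = 1`
otherwise — so a gain of 1 reproduces the control arm exactly under matched
seeds. The punch score defaults to quality relative to the elite reference
maximum; a model-based scorer (full waveform + conformance) is available
and used by the pipeline when trained models are passed. The month of
training maps to 12 sessions of 20 punches. The preset
`base_learning_rate = 0.0065`, `feedback_gain = 3.5`, starting u = 0.30 is
calibrated so the control arm gains roughly 8.5 % mean quality over the
month and the feedback arm roughly twice that; the human-subject
percentages of the original study are qualitative anchors for this preset,
not asserted outcomes.

## Problem sizes and defaults

The pipeline defaults are scaled down so all three series run in minutes on
one CPU: 4 elite boxers with 50 training + 30 test punches per hand
(full-scale study counts, 500/300 per hand for 10 boxers, are plain config
values), 10 boxers per learning arm, 100-replicate properties for the
stochastic claims. The second-series cohort spans skill 0.3–0.8: a strictly
low-skill cohort scores near-zero conformance against an elite-trained
model and collapses the x-axis of the quality–conformance fit.

## Known limitations

- The conformance score of a binary classifier is a design choice; the
  study never defines its per-punch "degree of coincidence" operationally.
- Detection timing conventions (onset at the last sub-threshold sample,
  sample-resolution event times) are exact on the generator's grid but
  would carry sub-sample bias on real, unquantized signals.
- The learning model is the simplest mechanism producing monotone
  improvement; it encodes no retention, fatigue or motor-control realism.
- With 5 % positives at desk scale the test-set F1 of the trained models is
  modest and seed-dependent; the pipeline reports it honestly rather than
  tuning toward a target.
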