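# punchlab

Wrist-IMU and force-pad analytics for straight boxing punches: a desk-scale,
fully synthetic re-implementation of an "optimal punch" study pipeline.
It is aimed at sports-biomechanics and wearable-sensor researchers who want a
tested, seeded sandbox for punch-quality statistics, best-punch
classification and biofeedback training protocols.

## The problem and the model

A boxer punches a pad while wearing a 6-channel wrist IMU (3-axis
acceleration, ±16 g; 3-axis angular rate, ±2000 deg/s). The pad's air
chamber records a force curve per punch. From each punch we extract:

- the peak force **F** (N) and the rise time **t** (s) from the onset of the
  force increase to its maximum,
- the fist speed at impact **v** (m/s), integrated from the punch-axis
  acceleration (the accelerometer Y axis points along the punch),

and form the study's statistics:

```
F_eff = F / t           effective punch force (N/s)
q_p   = F_eff · v       punch quality
q_rp  = q_p / q_p,max   relative quality within a boxer's series
```

The top 5 % of an elite cohort's punches by `q_p` define the positive class
of a multilayer perceptron (600 → 512 → 256 → 128 → 64 → 2, sigmoid on every
layer, per-node binary cross-entropy, Adam with lr = 0.001, β₁ = 0.9,
β₂ = 0.999). The 600 inputs are the raw 6 × 100-sample window ending at
impact. A punch's *conformance* x ∈ [0, 1] is the normalized best-punch
output of this model; relative quality is regressed on conformance with a
degree-2 polynomial. Five LEDs on the pad quantize the score into equal
bins (1 LED = worst, 5 = best) for real-time biofeedback, and a seeded
motor-learning simulation compares a feedback arm against a control arm
over a month of training.

There are no deposited recordings: `punchlab.synthetic` generates seeded,
ground-truthed cohorts whose (F, t, v) envelopes are anchored to the
published elite best-punch tables (`punchlab.reference`).

## Worked example

```python
from punchlab import pipeline

cfg = pipeline.RunConfig(seed=42)          # scaled-down defaults: 4 boxers,
res1 = pipeline.run_series1(cfg)           # 50 train + 30 test punches/hand
print(res1.best_punch_tables["right"].round(3))
res2 = pipeline.run_series2(cfg, res1.models)
print([round(float(c), 3) for c in res2.fit.coefficients], round(res2.fit.r, 3))
comp = pipeline.run_series3(cfg)
print(comp.feedback_stats["mean"], comp.control_stats["mean"], comp.mean_ratio)
```

prints (right hand, per-boxer best punch of the elite training sessions):

```
  boxer      F_N   t_s    F_eff  v_mps        q_p
boxer01 1241.954 0.192 6468.511 10.918  70624.570
boxer02 1289.152 0.176 7324.729 11.306  82816.651
boxer03 1345.534 0.152 8852.194 12.096 107075.043
boxer04 1347.553 0.150 8983.690 11.737 105437.980
```

Every row stays inside the published elite envelopes (F 790–1403 N,
t 0.138–0.984 s), and `q_p` orders the boxers by how hard *and* fast they
punch. The 10-fold cross-validation of the right-hand model averages 96.5 %
accuracy with 5 of 10 folds at 100 % — the characteristic mix of perfect and
imperfect folds for a 5 %-positive class at this sample size. The series-2
fit on a novice-to-intermediate cohort gives coefficients
`[0.693, 1.671, -1.433]` with r = 0.207 > 0: punches that conform more
closely to the model are relatively better. The series-3 simulation improves
mean punch quality by 16.3 % in the feedback arm vs 10.4 % in the control
arm (ratio 1.58) for this seed.

The same stages are scriptable from a shell:

```bash
punchlab simulate --boxers 2 --punches 50 --out data/
punchlab detect --in data/boxer01_right_stream.csv --out events.csv
punchlab series1 --seed 42 --out results/
punchlab series3 --seed 42 --out results/
```

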