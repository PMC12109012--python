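# Methods

This note documents the models implemented in fallkit, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic experiments do and do not demonstrate.

## Signal conventions

All accelerations are kept in g internally (1 g = 9.81 m/s² exactly;
conversion to m/s² happens only at reporting boundaries, so the 3 g trigger
prints as 29.43 m/s²). Sensor counts from an ADXL345-class part (±16 g,
13-bit) convert at 2·16/2¹³ = 1/256 g per count; the synthetic writer uses
the inverse quantization, which perturbs a round-tripped magnitude by less
than √3/256 g.

Downsampling from the 200 Hz dataset rate to the 20 Hz firmware rate is
plain decimation (every 10th sample, starting at index 0) with no
anti-alias filter: decimation reproduces exactly the samples a native 20 Hz
capture would have taken, and keeps the 4-s window at exactly 80 samples.
Human-movement energy is concentrated well below 10 Hz, so the aliasing
risk is limited to the impact spike itself, which decimation preserves by
construction in the windowing step (see below). An optional low-pass could
be added ahead of decimation but is deliberately not the default.

Z-score normalization uses the *pooled population* statistics of every
sample of every training window (divide by N, one μ and σ for the whole
pool, not per window or per position). Pooled/population was chosen for
determinism and because a single (μ, σ) pair is what a deployed gateway
would store; the fitted statistics are frozen into the model checkpoint and
applied verbatim at inference. A zero-variance pool raises rather than
silently producing NaNs.

## Threshold detector

The streaming detector is a total function of (state, sample): a 40-sample
(2 s at 20 Hz) ring buffer in monitoring mode; a strict `sample > 3 g`
comparison arms capture ("surpasses" is read as strict inequality; at
exactly 3.0 g nothing fires). Capture collects the trigger plus 39 further
samples and emits a window laid out as 40 pre-trigger samples, the trigger
at index 40, and 39 post-trigger samples — the unavoidable off-by-one of
putting an odd anchor into an even-length window; trigger-at-40 is fixed in
`DetectorConfig`. After emission the ring restarts empty, so a later
window's history never reaches across the reset point. Crossings during an
ongoing capture do not re-trigger. Two edge rules the hardware description
leaves open are fixed as: (a) cold start — missing history is padded by
repeating the earliest available sample (the trigger itself if there is
none); (b) a trigger closer than 2 s to the end of the stream never
completes its capture and emits nothing.

`detect_events_offline` is an independently written left-to-right scan with
the same three rules; the test suite asserts element-wise equality of the
two implementations on 1,000 seeded random series, which is the main
correctness argument for the streaming state machine.

## Link and gateway

The radio link is modelled per packet: a window is cut into
`ceil(80/samples_per_packet)` packets (default 20 samples → 4 packets, a
configurable choice since the real payload split is firmware-defined), and
each packet is delivered on the first success among 1 + 3 independent
Bernoulli(1 − p) attempts, giving per-packet delivery 1 − p⁴. The gateway
places delivered payloads at their offsets and fills every missing sample
with the most recent valid one (LOCF; a missing prefix copies the first
valid sample). Zero delivered packets is a lost event and raises. One
seeded generator per call; no global random state.

## Classifier

Architecture and training hyperparameters are fixed configuration:
Conv1D(32, kernel 3) → ReLU → BatchNorm → Conv1D(64, kernel 3) → ReLU →
BatchNorm → MaxPool(2) → LSTM(32, return sequences) → Dropout(0.2) →
LSTM(32) → Dropout(0.2) → Dense(1); training with Adam (learning rate 1e-3,
the backend-default value), binary cross-entropy, 70 epochs, batch size 32,
decision threshold 0.5 with the boundary mapped to "fall". Valid (unpadded)
convolutions take the 80-sample input to 78 → 76 → 38 time steps into the
recurrent stage. Where the prose description of the layer stack is
ambiguous, ReLU is applied before batch normalization (the literal reading)
and a single max-pool follows the second conv block; per-conv pooling is
available as a config flag. Dropout is attached to each LSTM's output.

The network is implemented in-package in numpy (`fallkit.nn`): the layers
are small and the windows short, so a hand-written implementation with
explicit backpropagation is fast enough (a full 70-epoch run on ~500
windows takes under a minute on one CPU) and keeps the dependency footprint
to the scientific Python base. Details that matter for reproduction:
Glorot-uniform initialization everywhere, LSTM forget-gate bias initialized
to 1, batch-norm eps 1e-3 with exponential running statistics at momentum
0.9 (the faster-adapting value matters when training runs are only a few
hundred optimizer steps), Adam eps 1e-7, binary cross-entropy computed on
logits via the stable softplus form. Every gradient is validated against
central finite differences through the full network in `tests/test_nn.py`.
All randomness (init, shuffling, dropout) derives from the config seed;
identical seeds give bit-identical training histories.

## Windowing protocol

Fall traces contribute exactly one pattern: the 4-s native-rate segment
centered on the global magnitude maximum (earliest index on ties), clamped
at trace boundaries so the window keeps full length, then decimated by 10.
Because the segment starts at `peak − 400`, the peak sample lies on the
window's decimation grid and survives to the 20 Hz pattern. ADL traces
contribute up to three windows around their highest local maxima, selected
greedily by height with the constraint that the *clamped* windows do not
overlap (≥ 4 s between window starts) — the reproducible automation of what
was originally a visual inspection step. The magnitude is computed after
decimation; since the norm is a pointwise operation, decimating first and
computing the magnitude after is identical to the reverse order under plain
decimation, so the alignment convention is the only real choice.

Subject partitioning shuffles the sorted subject list with a seeded
generator and cuts 60/20/20 (6/2/2 at ten subjects); every pattern follows
its subject, and leakage is asserted on every partition.

## Evaluation and energy model

Metrics use the standard 2×2 confusion tabulation with fall as the positive
class; accuracy, sensitivity and specificity are percentages, rounded to
two decimals only at display. Zero-denominator metrics raise; the pipeline
report maps an undefined metric to `None` instead so single-class suites
(e.g. an all-ADL monitoring run) still produce a report. The two-stage
evaluator attributes each trace: no emitted window → predicted non-fall at
the threshold stage (a fall trace that never crosses 3 g is a
threshold-stage false negative); otherwise the classifier's verdict on the
emitted window(s) decides (any window classified as a fall marks the trace
a predicted fall).

The energy model is deliberately simple: autonomy = usable capacity /
average current. Defaults are the measured node currents (24.3 / 8.2 / 4.5
/ 56.2 mA for both-active / radio-suspended / sleep / transmitting) with a
1000 mAh battery at an 80% usable margin; the headline figure uses the
sleep current alone (0.8·1000/4.5 ≈ 177.8 → 178 h). A duty-cycle-weighted
variant folds in transmit bursts of 12 s per detected event at 56.2 mA for
scenario studies, with the event rate exposed as a parameter since the
resting figure assumes triggers are rare.

## Synthetic corpus

The generator defines the study conditions for every end-to-end test: 10
subjects, 15 fall traces (10 s) and 19 ADL traces (14 s) each at 200 Hz,
with ±5% per-subject amplitude jitter; per-trace seeds derive from (master
seed, subject index, trace index) so any trace is individually
regenerable. Falls draw an impact peak uniformly from 3.5–8 g, a free-fall
dip of 0.2–0.6 g lasting 0.3–0.5 s, and end resting at ≈1 g in a
fall-type-specific orientation (forward, lateral, backward-with-rotation,
backward-supine — the four directions of the real-time testbed). The
impact includes a 0.1-s plateau at the peak so the >3 g crossing survives
any 200→20 Hz decimation phase. ADLs (walk at ~2 Hz with 0.2–0.5 g
amplitude, sit/stand, lie-down with orientation change, bend) have their
envelopes clipped at 2.4 g, which with 0.03 g per-axis noise keeps them
below 3 g with overwhelming margin — the threshold stage's perfect
specificity on quiet ADLs is therefore by construction, and is the
scaffold on which the pipeline tests stand. With probability 0.05 an ADL
carries a distractor spike (3.4–3.8 g, no free-fall dip, no orientation
change): these cross the threshold and must be rejected by the classifier,
which is the non-trivial part of the confirmation task.

These parameter values are physiologically motivated choices of this
package (the dynamics they emulate — dip, >3 g impact, 2–4 s event span —
are the field's standard description of a fall signal); they are not fitted
to any dataset. Accordingly, passing the end-to-end tests shows that the
pipeline is internally consistent and that the classifier learns the
free-fall/impact/orientation contrast from data — it does not certify
performance on real falls, which are more variable (compensatory movements,
soft surfaces, syncope falls with low peaks) than either simulated-fall
datasets or this generator.

## Problem sizes

The default experiment trains on ~380 windows for 70 epochs (~1 min on one
CPU); the detector-equivalence and metric-recount properties use 1,000
seeded instances each; the link-delivery check uses 10,000 packets at 50%
loss. These sizes give stable statistics (3-standard-error bands on the
binomial checks) while keeping the full suite and the acceptance script
each within a few minutes.

## Known limitations

- No real-data evaluation ships with the package; SisFall files are read if
  supplied but are not downloaded or bundled.
- The link model is Bernoulli per attempt — no burst losses, fading, or
  payload-encoding effects.
- The classifier's numerics follow one fixed convention set (valid padding,
  ReLU-then-BN, single pool); other readings of the architecture prose are
  config options, not tested variants.
- The energy model ignores sensing-burst overhead above the sleep-state
  draw; its resting figure is exact only when events are rare.
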