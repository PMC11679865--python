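# Methods

`affectlstm` implements a subject-dependent EEG emotion classifier: an
attention-augmented two-layer LSTM whose five architecture/training
hyperparameters are chosen per subject by particle swarm optimization
(PSO), trained on baseline-relative time-domain features of 3-s EEG
windows. This note records the model, the protocol, the synthetic
benchmark and the design choices taken where the design was genuinely
open.

## Feature model

Each trial (63 s at 128 Hz in the DEAP layout, 60 s at 200 Hz in the SEED
layout) is cut into consecutive, non-overlapping 3-s windows. The first
window is the baseline — the pre-stimulus state for the 63-s layout, the
first 3 s of the viewing period for the 60-s layout — and every later
window becomes one example after element-wise subtraction of the baseline.
A 63-s trial therefore yields 21 windows of which 20 are examples
(40 trials → 800 examples per subject); a 60-s trial yields 20 windows of
which 19 are examples (45 trials → 855). Features are z-scored per channel.
Examples enter the network as `timesteps × channels` (384 × 32 or
600 × 32): time is the recurrence axis, with one channel vector per step.

Labels: continuous valence/arousal ratings in [1, 9] are thresholded at 5
into the four circumplex quadrants (HVHA/LVHA/LVLA/HVLA). The threshold
comparator is *strict* by default — a rating of exactly 5 counts as low —
because "5 as a threshold" does not itself fix the boundary; the
comparator is configurable and the mapping is deterministic and monotone
either way. Categorical {−1, 0, 1} trial labels map directly to
negative/neutral/positive.

Standardization scope: the default z-scores each channel over all of a
subject's feature windows before splitting, mirroring the per-subject
protocol this package reproduces. A leakage-safe alternative
(`standardize_scope="train_stats_channel"`) defers z-scoring until the
split is known and fits the statistics on the training partition only;
both modes are first-class.

## Classifier

Forward pipeline:

    LSTM₁ (sequence out) → BatchNorm → Dropout →
    LSTM₂ (sequence out) → BatchNorm → Dropout →
    additive attention over the LSTM₂ hidden sequence →
    concat(context vector, final hidden state) →
    Dense(tanh) → Dense(softmax)

The LSTM cell is the standard three-gate formulation

    f_t = σ(W_if x_t + W_hf h_{t−1} + b_f)
    i_t = σ(W_ii x_t + W_hi h_{t−1} + b_i)
    o_t = σ(W_io x_t + W_ho h_{t−1} + b_o)
    c̃_t = tanh(W_ic x_t + W_hc h_{t−1} + b_c)
    c_t = f_t ∘ c_{t−1} + i_t ∘ c̃_t
    h_t = o_t ∘ tanh(c_t)

with distinct candidate-gate parameters (W_ic, W_hc, b_c). Attention is
the additive concatenation score against the final hidden state h_n:

    score_t = v_aᵀ tanh(W_a [h_t ; h_n]),   a = softmax(score),
    c = Σ_t a_t h_t

v_a is a learned projection vector (not an additive bias); W_a has
`attn_dim` rows, defaulting to the second LSTM's unit count. Attention
attends over the *top* LSTM layer's hidden states, the layer that feeds
the head. The "without attention" ablation removes the score/context path
and feeds h_n alone to the dense head.

The network and its training are implemented directly in NumPy: exact
analytic reverse-mode gradients (checked against central finite
differences in the test suite), inverted dropout, batch normalization
over the feature axis with running statistics frozen at evaluation (so
inference is deterministic), and Adam. Order of the post-LSTM blocks is
normalize-then-dropout. Weights are Glorot-uniform; the forget-gate bias
starts at 1. One integer seed fixes initialization, dropout masks and
batch shuffling. Training keeps a snapshot of the parameters at the epoch
with the lowest validation loss and restores it at the end, so the
returned model is the one the selection criterion (minimum validation
cross-entropy) actually chose.

## Hyperparameter search

Five dimensions: units of LSTM₁ (1–200), units of LSTM₂ (1–200), dense
units (1–200), dropout rate (0.1–0.9), batch size (1–128). PSO with
inertia w = 0.2, cognitive c₁ = 0.3, social c₂ = 0.5, 15 particles, 10
iterations:

    v ← w·v + c₁ r₁ ∘ (p − x) + c₂ r₂ ∘ (g − x),   x ← x + v

with r₁, r₂ fresh uniform[0,1] per dimension per update. Choices where the
formulation is silent: per-dimension random draws (not per-particle
scalars); velocities clipped to ± the dimension range and positions
clamped to the bounds; velocities initialized uniform in ±10 % of each
range; synchronous updates (all fitnesses evaluated, then one global-best
refresh per iteration), which makes the global-best trace non-increasing
by construction and the whole evaluation log bit-reproducible from the
seed. Integer dimensions are searched continuously and rounded to the
nearest value only when a position is decoded for evaluation, keeping the
update algebra exact. Fitness evaluations are cached on the decoded
hyperparameters. A non-finite fitness is recorded as +∞; if the entire
first iteration is non-finite the search aborts with an error.

A note on the default coefficients: w = 0.2 with c₁ + c₂ = 0.8 is a
strongly damped setting suited to the 10-iteration budget it accompanies,
but it is not convergent in the PSO-theoretic sense — on long horizons the
particles collapse onto the global best and stagnate before reaching an
optimum's basin floor. The package's own long-horizon convergence check
(a bounds-normalized sphere, 30 particles × 200 iterations) therefore uses
the standard Clerc–Kennedy setting w = 0.7298, c₁ = c₂ = 1.4962, under
which the continuous dimension reaches the optimum to ~1e-12; the damped
defaults apply everywhere else.

Fitness = the minimum validation categorical cross-entropy reached when
training a model built from the decoded position, on a split fixed once
per subject before the swarm starts. The fitness closure is constructed
from the train/validation partitions only and exposes the indices it can
read, so the no-test-leakage property is asserted, not assumed. After the
search the final model is retrained from scratch with the winning
hyperparameters (reusing the winning particle's weights would entangle
the search and the final fit) and evaluated once on the test partition.

## Protocol and aggregation

Per subject: examples are shuffled with a seeded permutation and split
60 / 20 / 20 (floors for train and validation, remainder to test).
Reference training settings: 150 epochs, Adam at learning rate 1e-4,
categorical cross-entropy. Across subjects: mean/std/max/min of test
accuracies (std is the population form) and the element-wise sum of
confusion matrices.

## Synthetic benchmark

The generator emulates both array layouts with a signal model matched to
the feature pipeline: every trial is Gaussian noise (sd 1), and the
experimental windows of a trial additionally carry the trial's class
effect — a fixed per-class, per-channel amplitude offset plus a
class-specific sinusoid (6–30 Hz, inside the datasets' 4–45 Hz passband)
with per-trial random phase. The baseline window never carries the
effect, so baseline subtraction recovers it by construction. The `snr`
knob is effect amplitude over noise sd: 1.0 is the default operating
point, 4.0 is the "high SNR" condition used in the end-to-end recovery
experiments, and 0 removes class structure entirely. Quadrant ratings are
placed in the interiors (high ≈ 6.5–8.5, low ≈ 1.5–3.5) so the threshold
rule recovers the intended class exactly. What the generator does *not*
emulate: 1/f spectra, electrode covariance, artifacts, non-stationarity —
passing tests show the pipeline recovers the statistical structure it is
designed for, not that real EEG behaves this way.

### What the snr = 0 control actually measures

A finding worth stating plainly: with class effects removed, test accuracy
under the per-segment shuffled split stays far above chance (~0.87 at desk
scale, vs 0.25 for four balanced classes). The reason is structural, not a
bug: all 20 segments of a trial share the same subtracted baseline, so
every example carries a trial-specific "fingerprint", and with segments of
one trial scattered across train and test, a model can map fingerprint →
trial → label without any class signal. This is a property of the
baseline-subtraction + segment-shuffle protocol itself, which this package
reproduces faithfully; it is one reason segment-level-split accuracies in
this literature should be read with care. Two controls restore
chance level and are both tested: shuffling labels at the example level
(breaking the trial→label association), and the grouped per-trial split
option (`group_split=True`), which keeps every trial's segments in a
single partition.

## Desk-scale profile

Heavy experiments in the tests, the examples and the acceptance script
use a reduced profile chosen so a full subject run (search + final
training + evaluation) completes in about a minute on one CPU: recordings
of 8 trials × 8 channels × full 63-s length (160 examples of 384 × 8);
search space capped at 32 units with batch size 16–64; 5 particles × 3
iterations; 10-epoch fitness trainings; 30-epoch final training at Adam
learning rate 3e-3 in float32. The larger learning rate compensates for
the short schedule at this scale; the reference defaults (150 epochs,
lr 1e-4) remain the package defaults. End-to-end experiments report means
over 3–5 generator/run seeds.

## Numerical choices and degenerate inputs

- Equation-level contracts (`lstm_step`, attention ops) run in float64;
  the packed training path agrees with them to machine precision and is
  float32 by default for speed.
- Z-scoring guards constant channels with an epsilon (yielding zeros);
  the guard can be disabled to make a constant channel a hard error.
- Softmax and sigmoid use max-shifted / piecewise stable forms.
- Trials whose length is not a multiple of the window are rejected by
  default (both real layouts are exact multiples, so a remainder signals
  corruption); truncation must be requested explicitly.
- Dataset readers reject wrong shapes rather than coercing them, never
  permute channels, and report expected vs found shapes in errors.

## Known limitations

- Subject-dependent only; no cross-subject transfer or session-level
  generalization is attempted.
- The per-segment shuffled split inherits the within-trial leakage
  discussed above; use `group_split=True` for a conservative estimate.
- Training is CPU NumPy: faithful and exact, but not fast at the full
  study scale (150 fitness trainings × 150 epochs per subject).
- The SEED-layout reader needs the 32-channel subset as input; the
  published 62-channel montage order and per-session label sequence are
  shipped as overridable defaults.
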