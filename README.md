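# affectlstm

Subject-dependent emotion estimation from EEG with an attention-based
LSTM whose hyperparameters are tuned per subject by particle swarm
optimization (PSO).

Emotion recognition from scalp EEG commonly frames affect on Russell's
circumplex: valence (pleasantness) and arousal (intensity), rated 1–9,
thresholded at 5 into four quadrant classes (HVHA, LVHA, LVLA, HVLA);
three-class negative/neutral/positive labels are supported for the
60-s-trial layout. The package is for researchers who want a transparent,
fully inspectable reference implementation of this pipeline — every
gradient is analytic NumPy, every random draw is seeded — plus a synthetic
class-conditional EEG generator so the entire method can be exercised and
tested without access-restricted datasets.

## Method

1. **Features.** Each trial is cut into 3-s windows; the first window is
   the baseline and each later window becomes one example after
   element-wise baseline subtraction (amplitude change relative to the
   pre-stimulus state), then per-channel z-scoring. A 63-s, 128 Hz trial
   gives 20 examples of 384 timesteps × 32 channels.
2. **Classifier.** Two stacked LSTM layers (batch-norm + dropout after
   each), additive attention over the top layer's hidden sequence —
   `score_t = v_aᵀ tanh(W_a [h_t ; h_n])`, softmax weights, context
   `c = Σ_t a_t h_t` — concatenated with the final hidden state `h_n`,
   then a tanh dense layer and a softmax head trained with categorical
   cross-entropy and Adam.
3. **Search.** PSO (`v ← w v + c₁ r₁ (p − x) + c₂ r₂ (g − x)`,
   `x ← x + v`; w=0.2, c₁=0.3, c₂=0.5, 15 particles, 10 iterations) over
   five dimensions: LSTM₁ units (1–200), LSTM₂ units (1–200), dense units
   (1–200), dropout (0.1–0.9), batch size (1–128). Fitness is the best
   validation cross-entropy of a model trained from the decoded position
   on a fixed 60/20/20 shuffled split; the winner is retrained from
   scratch and scored once on the test partition.

Ablations: `no_attention` (context path removed) and `fixed_params`
(reference configuration 128/64/16 units, dropout 0.2, batch 32; no
search). See `docs/methods.md` for assumptions, design decisions and what
the synthetic benchmark does and does not show.

## Worked example

```python
import affectlstm as al

rec = al.generate_recording(al.SynthConfig.desk(seed=1, snr=4.0))
report = al.run_subject(rec, "proposed", al.desk_profile(), seed=1)
print(report.best_hyperparams)
print(report.accuracy)
```

Running `python examples/subject_experiment.py` (the same computation,
a minute or two on one CPU) prints:

```
subject synth-deap-1
  swarm evaluations: 15 (5 particles x 3 iterations)
  global best validation loss per iteration:
    iteration 1: 0.0257
    iteration 2: 0.0244
    iteration 3: 0.0244
  best hyperparameters: {'units1': 29, 'units2': 17, 'dense_units': 21,
                         'dropout_rate': 0.5692..., 'batch_size': 32}
  test accuracy: 1.0000
  confusion matrix (rows = true quadrant):
  [[10  0  0  0]
   [ 0 13  0  0]
   [ 0  0  5  0]
   [ 0  0  0  4]]
```

The loss trace is the swarm's global best validation cross-entropy after
each iteration (non-increasing by construction); the accuracy is on the
20 % of windows withheld from both training and the search. Other
examples: `simulate_and_extract.py` (generator + feature counts),
`equation_walkthrough.py` (cell/attention equations on toy inputs),
`pso_on_sphere.py` (swarm behaviour on a known objective).

A thin CLI wraps the same calls:

```bash
affectlstm simulate --out recs/ --subjects 3 --desk --snr 4 --seed 0
affectlstm experiment recs/ --out results/ --mode proposed --seed 0
```

Real dataset files are read when present — `read_deap` (pickle or MATLAB
per-subject mapping) and `read_seed` (session files; pass the 32-channel
subset) — but nothing in the package requires them.

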