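"""Generate a synthetic subject recording and extract baseline-relative features.

The generator draws a quadrant-labelled recording in the 40-trial, 63-s
layout: each trial starts with a 3-s noise-only baseline window, and the
viewing windows add that trial's class effect on top of the noise.  Feature
extraction cuts 3-s windows, subtracts the baseline and z-scores per
channel.
"""

import affectlstm as al

cfg = al.SynthConfig(seed=0, snr=2.0)  # full 40 x 32 x 8064 layout
rec = al.generate_recording(cfg)
print(f"recording: {rec.data.shape} at {rec.sampling_rate} Hz, "
      f"tag={rec.dataset_tag}")
print(f"ratings (first 3 trials):\n{rec.labels[:3].round(2)}")

fs = al.build_feature_set(rec)
print(f"\nfeatures: {fs.features.shape}  "
      "(examples x timesteps x channels; 40 trials x 20 windows = 800)")
for cid, name in enumerate(fs.class_names):
    print(f"  {name}: {(fs.class_ids == cid).sum()} examples")
# Each example is one 3-s window of amplitude change relative to the
# trial's baseline; its label is the trial's valence-arousal quadrant.
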