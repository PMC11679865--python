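"""Walk the cell and attention equations on tiny hand-sized inputs.

Shows one gated cell update (forget/input/output gates, tanh candidate)
and the additive attention pipeline: scores against the final hidden
state, softmax weights, and the context vector.
"""

import numpy as np

from affectlstm import (
    AttentionParams,
    LSTMCellParams,
    attention_scores,
    attention_weights,
    context_vector,
    lstm_step,
)

# --- one cell step with zero weights: every gate is sigmoid(0) = 0.5
params = LSTMCellParams.zeros(hidden=1, inputs=1)
h, c = lstm_step(params, np.array([2.0]), np.array([0.0]), np.array([1.0]))
print(f"zero-weight cell: c_t = {c[0]:.4f} (= 0.5 * c_prev), "
      f"h_t = {h[0]:.4f} (= 0.5 * tanh(c_t))")

# --- attention over a 4-step, 2-unit hidden sequence
rng = np.random.default_rng(0)
H = rng.normal(size=(4, 2))
attn = AttentionParams(W_a=rng.normal(size=(3, 4)), v_a=rng.normal(size=3))
scores = attention_scores(H, attn)
weights = attention_weights(scores)
ctx = context_vector(H, weights)
print(f"scores:  {scores.round(4)}")
print(f"weights: {weights.round(4)}  (sum = {weights.sum():.6f})")
print(f"context: {ctx.round(4)}")
# The weights say how much each timestep contributes to the context vector
# that the classifier concatenates with the final hidden state.
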