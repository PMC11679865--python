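"""The attention-LSTM emotion classifier.

Two views of the same mathematics live here:

* **Equation-level contracts** — :func:`lstm_step` (the gated cell update
  with forget/input/output gates and a tanh candidate state),
  :func:`attention_scores` / :func:`attention_weights` /
  :func:`context_vector` (additive concatenation-score attention against
  the final hidden state).  These operate on single sequences with
  explicit per-gate parameters and exist so the vectorised training path
  can be checked against them exactly.
* **The trainable classifier** — :class:`AttentionLSTMClassifier`, built by
  :func:`build_model` from a :class:`ModelSpec`: two stacked LSTM layers,
  each followed by batch normalization and dropout, additive attention over
  the top layer's hidden-state sequence, concatenation of the context
  vector with the final hidden state, a tanh dense layer and a softmax
  head.  Setting ``attention=False`` removes the attention/context path
  (final hidden state only) for the ablation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError
from . import nn

__all__ = [
    "LSTMCellParams", "lstm_step",
    "AttentionParams", "attention_scores", "attention_weights",
    "context_vector",
    "ModelSpec", "AttentionLSTMClassifier", "build_model",
]


# ---------------------------------------------------------------------------
# equation-level LSTM cell


@dataclass
class LSTMCellParams:
    """Per-gate LSTM parameters, input-weight matrices ``(hidden, input)``.

    Gates: f (forget), i (input), o (output); c denotes the tanh candidate
    cell state, which carries its own distinct parameters.
    """

    W_if: np.ndarray
    W_ii: np.ndarray
    W_io: np.ndarray
    W_ic: np.ndarray
    W_hf: np.ndarray
    W_hi: np.ndarray
    W_ho: np.ndarray
    W_hc: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        h, x = self.W_if.shape
        for name in ("W_if", "W_ii", "W_io", "W_ic"):
            if getattr(self, name).shape != (h, x):
                raise ShapeError(f"{name} must be ({h}, {x})")
        for name in ("W_hf", "W_hi", "W_ho", "W_hc"):
            if getattr(self, name).shape != (h, h):
                raise ShapeError(f"{name} must be ({h}, {h})")
        for name in ("b_f", "b_i", "b_o", "b_c"):
            if getattr(self, name).shape != (h,):
                raise ShapeError(f"{name} must be ({h},)")

    @property
    def hidden(self) -> int:
        return self.W_if.shape[0]

    @classmethod
    def zeros(cls, hidden: int, inputs: int) -> "LSTMCellParams":
        z = lambda *s: np.zeros(s)
        return cls(*(z(hidden, inputs) for _ in range(4)),
                   *(z(hidden, hidden) for _ in range(4)),
                   *(z(hidden) for _ in range(4)))

    @classmethod
    def from_packed(cls, Wx: np.ndarray, Wh: np.ndarray,
                    b: np.ndarray) -> "LSTMCellParams":
        """Unpack an :class:`affectlstm.nn.LSTMLayer`'s column-packed
        (forget, input, output, candidate) weights into per-gate form."""
        H = Wh.shape[0]
        f, i, o, c = (slice(k * H, (k + 1) * H) for k in range(4))
        return cls(
            W_if=np.asarray(Wx[:, f].T, dtype=np.float64),
            W_ii=np.asarray(Wx[:, i].T, dtype=np.float64),
            W_io=np.asarray(Wx[:, o].T, dtype=np.float64),
            W_ic=np.asarray(Wx[:, c].T, dtype=np.float64),
            W_hf=np.asarray(Wh[:, f].T, dtype=np.float64),
            W_hi=np.asarray(Wh[:, i].T, dtype=np.float64),
            W_ho=np.asarray(Wh[:, o].T, dtype=np.float64),
            W_hc=np.asarray(Wh[:, c].T, dtype=np.float64),
            b_f=np.asarray(b[f], dtype=np.float64),
            b_i=np.asarray(b[i], dtype=np.float64),
            b_o=np.asarray(b[o], dtype=np.float64),
            b_c=np.asarray(b[c], dtype=np.float64),
        )


def lstm_step(
    params: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update.

    f = sigma(W_if x + W_hf h + b_f),  i = sigma(W_ii x + W_hi h + b_i),
    o = sigma(W_io x + W_ho h + b_o),  c~ = tanh(W_ic x + W_hc h + b_c),
    c_t = f * c_prev + i * c~,  h_t = o * tanh(c_t).
    """
    x_t, h_prev, c_prev = (np.asarray(v, dtype=np.float64)
                           for v in (x_t, h_prev, c_prev))
    if x_t.shape != (params.W_if.shape[1],):
        raise ShapeError(
            f"x_t must be ({params.W_if.shape[1]},), got {x_t.shape}")
    if h_prev.shape != (params.hidden,) or c_prev.shape != (params.hidden,):
        raise ShapeError(f"state vectors must be ({params.hidden},)")
    f = nn.sigmoid(params.W_if @ x_t + params.W_hf @ h_prev + params.b_f)
    i = nn.sigmoid(params.W_ii @ x_t + params.W_hi @ h_prev + params.b_i)
    o = nn.sigmoid(params.W_io @ x_t + params.W_ho @ h_prev + params.b_o)
    c_tilde = np.tanh(params.W_ic @ x_t + params.W_hc @ h_prev + params.b_c)
    c_t = f * c_prev + i * c_tilde
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# equation-level attention


@dataclass
class AttentionParams:
    """W_a maps the concatenated (h_t ; h_n) pair; v_a projects to a scalar."""

    W_a: np.ndarray  # (attn_dim, 2 * hidden)
    v_a: np.ndarray  # (attn_dim,)

    def __post_init__(self) -> None:
        self.W_a = np.asarray(self.W_a, dtype=np.float64)
        self.v_a = np.asarray(self.v_a, dtype=np.float64)
        if self.W_a.ndim != 2 or self.v_a.ndim != 1:
            raise ShapeError("W_a must be a matrix and v_a a vector")
        if self.W_a.shape[0] != self.v_a.shape[0]:
            raise ShapeError("v_a length must equal the rows of W_a")


def attention_scores(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """score_t = v_a . tanh(W_a [h_t ; h_n]) for every step of ``H (n, hidden)``."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ShapeError("H must be (n >= 1, hidden)")
    if params.W_a.shape[1] != 2 * H.shape[1]:
        raise ShapeError(
            f"W_a columns ({params.W_a.shape[1]}) must equal "
            f"2 * hidden ({2 * H.shape[1]})")
    h_n = H[-1]
    concat = np.concatenate([H, np.broadcast_to(h_n, H.shape)], axis=1)
    return np.tanh(concat @ params.W_a.T) @ params.v_a


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Softmax of the scores over the time axis."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ShapeError("scores must be finite")
    return nn.softmax(scores, axis=-1)


def context_vector(H: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of the hidden states: c = sum_t a_t h_t."""
    H = np.asarray(H, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    if a.shape != (H.shape[0],):
        raise ShapeError(f"weights must be ({H.shape[0]},), got {a.shape}")
    return a @ H


# ---------------------------------------------------------------------------
# the classifier


@dataclass
class ModelSpec:
    """Architecture hyperparameters; the first five are the searched ones."""

    units1: int
    units2: int
    dense_units: int
    dropout_rate: float
    num_classes: int
    timesteps: int
    channels: int
    attention: bool = True
    attn_dim: int | None = None  # defaults to units2

    def __post_init__(self) -> None:
        for name in ("units1", "units2", "dense_units"):
            v = getattr(self, name)
            if not (1 <= v <= 200) or int(v) != v:
                raise ValueError(f"{name} must be an integer in [1, 200], got {v}")
        if not (0.1 <= self.dropout_rate <= 0.9):
            raise ValueError(
                f"dropout_rate must be in [0.1, 0.9], got {self.dropout_rate}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.timesteps < 1 or self.channels < 1:
            raise ValueError("timesteps and channels must be >= 1")
        if self.attn_dim is None:
            self.attn_dim = self.units2


#: The fixed-hyperparameter baseline configuration (no swarm search).
FIXED_BASELINE = {"units1": 128, "units2": 64, "dense_units": 16,
                  "dropout_rate": 0.2, "batch_size": 32}


class AttentionLSTMClassifier:
    """Two-layer LSTM with additive attention and a softmax head.

    The single ``seed`` fixes parameter initialization and the dropout
    stream.  In evaluation mode (dropout off, normalization statistics
    frozen) the forward map is deterministic.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        ss = np.random.SeedSequence(seed)
        init_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        s = spec
        self.lstm1 = nn.LSTMLayer(s.channels, s.units1, init_rng, dtype)
        self.bn1 = nn.BatchNorm(s.units1, dtype)
        self.drop1 = nn.Dropout(s.dropout_rate, drop_rng)
        self.lstm2 = nn.LSTMLayer(s.units1, s.units2, init_rng, dtype)
        self.bn2 = nn.BatchNorm(s.units2, dtype)
        self.drop2 = nn.Dropout(s.dropout_rate, drop_rng)
        if s.attention:
            self.attn = nn.AdditiveAttention(s.units2, s.attn_dim, init_rng, dtype)
            head_in = 2 * s.units2
        else:
            self.attn = None
            head_in = s.units2
        self.dense = nn.Dense(head_in, s.dense_units, init_rng, "tanh", dtype)
        self.head = nn.Dense(s.dense_units, s.num_classes, init_rng, None, dtype)

    @property
    def layers(self) -> list[nn.Layer]:
        out = [self.lstm1, self.bn1, self.drop1, self.lstm2, self.bn2,
               self.drop2]
        if self.attn is not None:
            out.append(self.attn)
        return out + [self.dense, self.head]

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=self.dtype)
        H = self.drop1.forward(self.bn1.forward(self.lstm1.forward(X), train), train)
        H = self.drop2.forward(self.bn2.forward(self.lstm2.forward(H), train), train)
        if self.attn is not None:
            context, hn = self.attn.forward(H)
            z = np.concatenate([context, hn], axis=1)
        else:
            z = H[:, -1]
        return nn.softmax(self.head.forward(self.dense.forward(z)), axis=1)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray) -> float:
        """Training-mode forward, then exact backprop; returns the batch loss."""
        probs = self.forward(X, train=True)
        loss = nn.cross_entropy(probs, y)
        B = len(y)
        dlogits = probs.astype(self.dtype)
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        self.zero_grad()
        dz = self.dense.backward(self.head.backward(dlogits))
        if self.attn is not None:
            U2 = self.spec.units2
            dH = self.attn.backward(dz[:, :U2], dz[:, U2:])
        else:
            dH = np.zeros_like(self.lstm2.Hseq)
            dH[:, -1] = dz
        dH = self.bn2.backward(self.drop2.backward(dH))
        dH = self.drop1.backward(self.lstm2.backward(dH))
        self.lstm1.backward(self.bn1.backward(dH))
        return loss

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [self.forward(X[i:i + batch_size], train=False)
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # weight snapshots (for best-validation restoration)

    def get_state(self) -> list[np.ndarray]:
        arrays = [p for p, _ in self.parameters()]
        arrays += [self.bn1.running_mean, self.bn1.running_var,
                   self.bn2.running_mean, self.bn2.running_var]
        return [a.copy() for a in arrays]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = [p for p, _ in self.parameters()]
        arrays += [self.bn1.running_mean, self.bn1.running_var,
                   self.bn2.running_mean, self.bn2.running_var]
        for dst, src in zip(arrays, state):
            dst[...] = src


def build_model(spec: ModelSpec, seed: int = 0,
                dtype=np.float32) -> AttentionLSTMClassifier:
    """Instantiate the classifier for a validated :class:`ModelSpec`."""
    return AttentionLSTMClassifier(spec, seed=seed, dtype=dtype)
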