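"""Minimal NumPy neural-network layers with exact reverse-mode gradients.

Only what the attention-LSTM classifier needs: an LSTM layer unrolled over
time (backpropagation through time), batch normalization over the feature
axis, inverted dropout, dense layers, the additive attention block, a
softmax cross-entropy head and Adam.  Each layer caches its forward
activations and exposes ``backward`` returning the input gradient while
accumulating parameter gradients in matching ``d<name>`` arrays.

Gradients are plain analytic derivatives (no autodiff); the test suite
checks them against finite differences.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs; gradient arrays are accumulated in place."""
        return []

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


class LSTMLayer(Layer):
    """Standard LSTM unrolled over ``(batch, time, features)`` input.

    Gate parameters are packed column-wise in order (forget, input, output,
    candidate): ``Wx (in, 4H)``, ``Wh (H, 4H)``, ``b (4H,)``.  The forget
    gate bias starts at 1 (common initialization easing early gradient flow).
    Returns the full hidden-state sequence.
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.input_size, self.hidden = input_size, hidden
        self.Wx = glorot(rng, (input_size, 4 * hidden), dtype)
        self.Wh = glorot(rng, (hidden, 4 * hidden), dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[:hidden] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.hidden
        self.X = X
        # input projection for every timestep in one matmul
        ZX = (X.reshape(B * T, -1) @ self.Wx).reshape(B, T, 4 * H) + self.b
        self.gates = np.empty((B, T, 4 * H), dtype=X.dtype)
        self.C = np.empty((B, T, H), dtype=X.dtype)
        self.Hseq = np.empty((B, T, H), dtype=X.dtype)
        h = np.zeros((B, H), dtype=X.dtype)
        c = np.zeros((B, H), dtype=X.dtype)
        for t in range(T):
            z = ZX[:, t] + h @ self.Wh
            f = sigmoid(z[:, :H])
            i = sigmoid(z[:, H:2 * H])
            o = sigmoid(z[:, 2 * H:3 * H])
            g = np.tanh(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            self.gates[:, t, :H] = f
            self.gates[:, t, H:2 * H] = i
            self.gates[:, t, 2 * H:3 * H] = o
            self.gates[:, t, 3 * H:] = g
            self.C[:, t] = c
            self.Hseq[:, t] = h
        return self.Hseq

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X, H = self.X, self.hidden
        B, T, _ = X.shape
        dZ = np.empty((B, T, 4 * H), dtype=X.dtype)
        dh_next = np.zeros((B, H), dtype=X.dtype)
        dc_next = np.zeros((B, H), dtype=X.dtype)
        WhT = self.Wh.T
        for t in range(T - 1, -1, -1):
            f = self.gates[:, t, :H]
            i = self.gates[:, t, H:2 * H]
            o = self.gates[:, t, 2 * H:3 * H]
            g = self.gates[:, t, 3 * H:]
            c = self.C[:, t]
            tc = np.tanh(c)
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = dZ[:, t]
            if t > 0:
                dz[:, :H] = (dc * self.C[:, t - 1]) * f * (1 - f)
            else:
                dz[:, :H] = 0.0  # c_prev is the zero initial state
            dz[:, H:2 * H] = (dc * g) * i * (1 - i)
            dz[:, 2 * H:3 * H] = do * o * (1 - o)
            dz[:, 3 * H:] = (dc * i) * (1 - g * g)
            dh_next = dz @ WhT
            dc_next = dc * f
        # parameter gradients in three large matmuls
        flat_dZ = dZ.reshape(B * T, 4 * H)
        self.dWx += X.reshape(B * T, -1).T @ flat_dZ
        h_prev_seq = np.concatenate(
            [np.zeros((B, 1, H), dtype=X.dtype), self.Hseq[:, :-1]], axis=1)
        self.dWh += h_prev_seq.reshape(B * T, H).T @ flat_dZ
        self.db += flat_dZ.sum(axis=(0))
        return (flat_dZ @ self.Wx.T).reshape(X.shape)


class BatchNorm(Layer):
    """Normalize each feature over the (batch, time) axes.

    Running statistics (momentum 0.9) are frozen in evaluation mode, making
    inference deterministic.
    """

    def __init__(self, features: int, dtype=np.float32,
                 momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(features, dtype=dtype)
        self.beta = np.zeros(features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(features, dtype=dtype)
        self.running_var = np.ones(features, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        if train:
            axes = tuple(range(X.ndim - 1))
            mean = X.mean(axis=axes)
            var = X.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            self.inv_std = 1.0 / np.sqrt(var + self.eps)
            self.xhat = (X - mean) * self.inv_std
            self.n = X.size // X.shape[-1]
            return self.gamma * self.xhat + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * (X - self.running_mean) * inv + self.beta

    def backward(self, dY: np.ndarray) -> np.ndarray:
        axes = tuple(range(dY.ndim - 1))
        self.dgamma += (dY * self.xhat).sum(axis=axes)
        self.dbeta += dY.sum(axis=axes)
        dxhat = dY * self.gamma
        # standard batch-norm backward over the pooled (batch, time) axis
        return (self.inv_std / self.n) * (
            self.n * dxhat
            - dxhat.sum(axis=axes)
            - self.xhat * (dxhat * self.xhat).sum(axis=axes)
        )


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self.mask = None
            return X
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(X.shape) < keep).astype(X.dtype) / keep
        return X * self.mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return dY if self.mask is None else dY * self.mask


class Dense(Layer):
    def __init__(self, input_size: int, output_size: int,
                 rng: np.random.Generator, activation: str | None = None,
                 dtype=np.float32):
        self.W = glorot(rng, (input_size, output_size), dtype)
        self.b = np.zeros(output_size, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, X: np.ndarray) -> np.ndarray:
        self.X = X
        out = X @ self.W + self.b
        if self.activation == "tanh":
            out = np.tanh(out)
        self.out = out
        return out

    def backward(self, dY: np.ndarray) -> np.ndarray:
        if self.activation == "tanh":
            dY = dY * (1.0 - self.out * self.out)
        self.dW += self.X.T @ dY
        self.db += dY.sum(axis=0)
        return dY @ self.W.T


class AdditiveAttention(Layer):
    """Concatenation-score attention against the final hidden state.

    score_t = v_a . tanh(W_a [h_t ; h_n]); weights = softmax over time;
    context = sum_t a_t h_t.  ``W_a`` is stored as ``(2H, A)`` so the
    forward pass is a single batched matmul.
    """

    def __init__(self, hidden: int, attn_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.Wa = glorot(rng, (2 * hidden, attn_dim), dtype)
        self.va = glorot(rng, (attn_dim, 1), dtype)[:, 0]
        self.dWa = np.zeros_like(self.Wa)
        self.dva = np.zeros_like(self.va)
        self.hidden = hidden

    def params(self):
        return [(self.Wa, self.dWa), (self.va, self.dva)]

    def forward(self, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B, T, U = H.shape
        hn = H[:, -1]
        concat = np.concatenate(
            [H, np.broadcast_to(hn[:, None, :], H.shape)], axis=2)
        self.H, self.concat = H, concat
        self.U_act = np.tanh(concat @ self.Wa)            # (B, T, A)
        scores = self.U_act @ self.va                     # (B, T)
        self.a = softmax(scores, axis=1)
        context = np.einsum("bt,btu->bu", self.a, H)
        return context, hn

    def backward(self, dcontext: np.ndarray, dhn: np.ndarray) -> np.ndarray:
        H, a = self.H, self.a
        B, T, U = H.shape
        dH = a[:, :, None] * dcontext[:, None, :]
        da = np.einsum("bu,btu->bt", dcontext, H)
        ds = a * (da - (a * da).sum(axis=1, keepdims=True))   # softmax jac
        du = ds[:, :, None] * self.va
        dpre = du * (1.0 - self.U_act * self.U_act)
        self.dva += np.einsum("bta,bt->a", self.U_act, ds)
        self.dWa += np.einsum("btc,bta->ca", self.concat, dpre)
        dconcat = dpre @ self.Wa.T
        dH += dconcat[:, :, :U]
        dH[:, -1] += dconcat[:, :, U:].sum(axis=1) + dhn
        return dH


def cross_entropy(probs: np.ndarray, y: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy for integer class labels."""
    p = np.clip(probs[np.arange(len(y)), y], eps, 1.0)
    return float(-np.mean(np.log(p)))


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
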