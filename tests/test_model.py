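"""Equation-level contracts of the LSTM cell and the attention block, and
behavioural properties of the assembled classifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectlstm.errors import ShapeError
from affectlstm.model import (
    AttentionLSTMClassifier,
    AttentionParams,
    LSTMCellParams,
    ModelSpec,
    attention_scores,
    attention_weights,
    build_model,
    context_vector,
    lstm_step,
)
from affectlstm.nn import AdditiveAttention, LSTMLayer


# ---------------------------------------------------------------------------
# LSTM cell


def test_lstm_step_zero_parameters_gives_half_gates():
    """With all weights zero: gates are sigmoid(0)=0.5, candidate tanh(0)=0,
    so c_t = 0.5 * c_prev and h_t = 0.5 * tanh(0.5 * c_prev)."""
    params = LSTMCellParams.zeros(hidden=3, inputs=2)
    v = np.array([0.4, -1.2, 2.0])
    h_t, c_t = lstm_step(params, np.array([5.0, -3.0]), np.zeros(3), v)
    np.testing.assert_allclose(c_t, 0.5 * v, rtol=0, atol=1e-15)
    np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * v), rtol=0, atol=1e-15)


def test_lstm_step_matches_scalar_hand_evaluation():
    """Single-unit cell against an independent step-by-step evaluation of the
    gate equations written with plain Python floats."""
    w = dict(W_if=0.5, W_ii=-0.3, W_io=0.2, W_ic=0.7,
             W_hf=0.1, W_hi=0.4, W_ho=-0.5, W_hc=0.6,
             b_f=0.05, b_i=-0.1, b_o=0.15, b_c=0.0)
    x, h_prev, c_prev = 0.8, -0.2, 0.5

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    f = sig(w["W_if"] * x + w["W_hf"] * h_prev + w["b_f"])
    i = sig(w["W_ii"] * x + w["W_hi"] * h_prev + w["b_i"])
    o = sig(w["W_io"] * x + w["W_ho"] * h_prev + w["b_o"])
    c_tilde = math.tanh(w["W_ic"] * x + w["W_hc"] * h_prev + w["b_c"])
    c_expect = f * c_prev + i * c_tilde
    h_expect = o * math.tanh(c_expect)

    params = LSTMCellParams(
        **{k: np.array([[v]]) for k, v in w.items() if k.startswith("W")},
        **{k: np.array([v]) for k, v in w.items() if k.startswith("b")},
    )
    h_t, c_t = lstm_step(params, np.array([x]), np.array([h_prev]),
                         np.array([c_prev]))
    assert abs(h_t[0] - h_expect) < 1e-12
    assert abs(c_t[0] - c_expect) < 1e-12


def test_lstm_step_cell_state_bound(rng):
    """|c_t| <= |c_prev| + 1 element-wise because the gates lie in (0,1) and
    the candidate in (-1,1)."""
    params = LSTMCellParams(
        *(rng.normal(size=(4, 3)) for _ in range(4)),
        *(rng.normal(size=(4, 4)) for _ in range(4)),
        *(rng.normal(size=4) for _ in range(4)),
    )
    for _ in range(50):
        x, h, c = rng.normal(size=3), rng.normal(size=4), rng.normal(size=4)
        h_t, c_t = lstm_step(params, x, h, c)
        assert (np.abs(c_t) <= np.abs(c) + 1 + 1e-12).all()
        assert (np.abs(h_t) < 1).all()  # |o| < 1 and |tanh| < 1


def test_lstm_step_shape_errors():
    params = LSTMCellParams.zeros(hidden=2, inputs=3)
    with pytest.raises(ShapeError):
        lstm_step(params, np.zeros(4), np.zeros(2), np.zeros(2))
    with pytest.raises(ShapeError):
        lstm_step(params, np.zeros(3), np.zeros(1), np.zeros(2))


def test_vectorised_lstm_layer_matches_equation_cell(rng):
    """The packed training-path layer, unpacked into per-gate parameters,
    reproduces the equation-level cell step for step over a sequence."""
    layer = LSTMLayer(input_size=3, hidden=4, rng=rng, dtype=np.float64)
    params = LSTMCellParams.from_packed(layer.Wx, layer.Wh, layer.b)
    X = rng.normal(size=(2, 6, 3))
    H = layer.forward(X)
    for b in range(2):
        h = np.zeros(4)
        c = np.zeros(4)
        for t in range(6):
            h, c = lstm_step(params, X[b, t], h, c)
            np.testing.assert_allclose(H[b, t], h, atol=1e-12)


# ---------------------------------------------------------------------------
# attention


def test_attention_scores_zero_matrix():
    params = AttentionParams(W_a=np.zeros((3, 4)), v_a=np.ones(3))
    scores = attention_scores(np.random.default_rng(0).normal(size=(5, 2)),
                              params)
    np.testing.assert_array_equal(scores, np.zeros(5))


def test_attention_scores_bounded_by_va_l1_norm(rng):
    params = AttentionParams(W_a=rng.normal(size=(3, 4)),
                             v_a=rng.normal(size=3))
    scores = attention_scores(rng.normal(size=(7, 2)), params)
    assert (np.abs(scores) <= np.abs(params.v_a).sum() + 1e-12).all()


def test_attention_scores_two_step_hand_oracle():
    """2-step, 1-unit toy against direct substitution: the concatenated pair
    is [h_t, h_n], so score_t = v_a * tanh(Wa0*h_t + Wa1*h_n)."""
    H = np.array([[0.3], [-0.5]])
    params = AttentionParams(W_a=np.array([[0.2, -0.4]]), v_a=np.array([1.5]))
    expect = np.array([
        1.5 * math.tanh(0.2 * 0.3 + (-0.4) * (-0.5)),
        1.5 * math.tanh(0.2 * (-0.5) + (-0.4) * (-0.5)),
    ])
    np.testing.assert_allclose(attention_scores(H, params), expect, atol=1e-12)


def test_attention_scores_dimension_mismatch():
    params = AttentionParams(W_a=np.zeros((3, 6)), v_a=np.zeros(3))
    with pytest.raises(ShapeError):
        attention_scores(np.zeros((4, 2)), params)  # needs W_a cols = 4


def test_attention_weights_uniform_and_saturated():
    np.testing.assert_allclose(attention_weights(np.full(5, 2.7)),
                               np.full(5, 0.2), atol=1e-15)
    w = attention_weights(np.array([0.0, 50.0]))
    assert w[1] > 1 - 1e-12 and w[0] < 1e-12


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-30, 30), min_size=1, max_size=12))
def test_attention_weights_normalised_and_permutation_equivariant(scores):
    scores = np.array(scores)
    w = attention_weights(scores)
    assert abs(w.sum() - 1.0) < 1e-12
    assert (w > 0).all()
    perm = np.random.default_rng(0).permutation(len(scores))
    np.testing.assert_allclose(attention_weights(scores[perm]), w[perm],
                               atol=1e-12)


def test_context_vector_selection_mean_and_brute_force(rng):
    H = rng.normal(size=(6, 3))
    one_hot = np.eye(6)[2]
    np.testing.assert_array_equal(context_vector(H, one_hot), H[2])
    np.testing.assert_allclose(context_vector(H, np.full(6, 1 / 6)),
                               H.mean(axis=0), atol=1e-12)
    a = attention_weights(rng.normal(size=6))
    expect = sum(a[t] * H[t] for t in range(6))  # brute-force loop oracle
    np.testing.assert_allclose(context_vector(H, a), expect, atol=1e-12)
    with pytest.raises(ShapeError):
        context_vector(H, np.full(5, 0.2))


def test_batched_attention_layer_matches_equation_ops(rng):
    """The model's batched attention block equals the per-sequence equation
    pipeline score -> softmax -> weighted sum."""
    layer = AdditiveAttention(hidden=3, attn_dim=4, rng=rng, dtype=np.float64)
    params = AttentionParams(W_a=layer.Wa.T.copy(), v_a=layer.va.copy())
    H = rng.normal(size=(5, 7, 3))
    context, hn = layer.forward(H)
    for b in range(5):
        a = attention_weights(attention_scores(H[b], params))
        np.testing.assert_allclose(context[b], context_vector(H[b], a),
                                   atol=1e-12)
        np.testing.assert_array_equal(hn[b], H[b, -1])


# ---------------------------------------------------------------------------
# assembled classifier


def _tiny_spec(**kw):
    base = dict(units1=5, units2=4, dense_units=3, dropout_rate=0.2,
                num_classes=3, timesteps=6, channels=2)
    base.update(kw)
    return ModelSpec(**base)


def test_model_outputs_probability_rows(rng):
    model = build_model(_tiny_spec(), seed=0)
    X = rng.normal(size=(9, 6, 2))
    probs = model.forward(X)
    assert probs.shape == (9, 3)
    np.testing.assert_allclose(probs.sum(axis=1), np.ones(9), atol=1e-6)
    assert (probs >= 0).all()


def test_fixed_baseline_architecture_builds():
    spec = ModelSpec(units1=128, units2=64, dense_units=16, dropout_rate=0.2,
                     num_classes=4, timesteps=10, channels=32)
    model = build_model(spec, seed=0)
    probs = model.forward(np.zeros((2, 10, 32)))
    assert probs.shape == (2, 4)


def test_attention_off_variant_drops_context_path(rng):
    on = build_model(_tiny_spec(), seed=0)
    off = build_model(_tiny_spec(attention=False), seed=0)
    assert on.dense.W.shape[0] == 2 * 4 and off.dense.W.shape[0] == 4
    assert off.attn is None
    probs = off.forward(rng.normal(size=(3, 6, 2)))
    np.testing.assert_allclose(probs.sum(axis=1), np.ones(3), atol=1e-6)


def test_probabilities_invariant_to_logit_shift(rng):
    model = build_model(_tiny_spec(), seed=0, dtype=np.float64)
    X = rng.normal(size=(4, 6, 2))
    before = model.forward(X)
    model.head.b += 3.7  # constant added to every pre-softmax logit
    np.testing.assert_allclose(model.forward(X), before, atol=1e-9)


def test_eval_mode_forward_is_deterministic(rng):
    model = build_model(_tiny_spec(), seed=0)
    X = rng.normal(size=(8, 6, 2)).astype(np.float32)
    model.loss_and_grads(X, np.zeros(8, dtype=int))  # touch train mode
    np.testing.assert_array_equal(model.forward(X), model.forward(X))


def test_modelspec_validation():
    with pytest.raises(ValueError):
        _tiny_spec(units1=0)
    with pytest.raises(ValueError):
        _tiny_spec(units2=201)
    with pytest.raises(ValueError):
        _tiny_spec(dropout_rate=0.05)
    assert _tiny_spec().attn_dim == 4  # defaults to units2


@pytest.mark.parametrize("attention", [True, False])
def test_backprop_matches_finite_differences(attention):
    """Analytic gradients of the full model (both LSTM layers, batch norm,
    attention, both dense layers) against central finite differences."""
    spec = _tiny_spec(units1=4, units2=3, timesteps=5, attention=attention)
    model = AttentionLSTMClassifier(spec, seed=3, dtype=np.float64)
    for layer in (model.drop1, model.drop2):
        layer.rate = 0.0  # deterministic loss surface for differencing
    rng = np.random.default_rng(7)
    X = rng.normal(size=(4, 5, 2))
    y = np.array([0, 1, 2, 1])

    def loss_at():
        from affectlstm.nn import cross_entropy

        return cross_entropy(model.forward(X, train=True), y)

    model.loss_and_grads(X, y)
    grads = [g.copy() for _, g in model.parameters()]
    eps = 1e-6
    check_rng = np.random.default_rng(11)
    for (param, _), grad in zip(model.parameters(), grads):
        flat = param.reshape(-1)
        idxs = check_rng.choice(flat.size, size=min(4, flat.size),
                                replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            up = loss_at()
            flat[i] = orig - eps
            down = loss_at()
            flat[i] = orig
            fd = (up - down) / (2 * eps)
            assert abs(fd - grad.reshape(-1)[i]) < 1e-6, (
                f"param shape {param.shape}, index {i}")
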