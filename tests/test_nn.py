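"""Numerical correctness of the network engine: gradients, optimizers."""

import numpy as np
import pytest

from surroneuron.nn import (
    Adam, Adamax, Conv1D, Dense, Dropout, Flatten, LSTM, Nadam, NmdaGate,
    OutputBias, RepeatVector, Sequential, TakeLast, make_optimizer,
)
from surroneuron.nn.losses import mae, mse


def numeric_vs_analytic(layers, in_shape, seed=0, eps=1e-6, n=4):
    rng = np.random.default_rng(seed)
    net = Sequential(layers, in_shape, seed=seed)
    x = rng.normal(size=(n,) + in_shape)
    y = rng.normal(size=(n,) + net.output_shape)

    def loss_value():
        out = net.forward(x, training=False)
        val, _ = mse(out, y)
        return val + net.regularization_loss()

    out = net.forward(x, training=False)
    _, dy = mse(out, y)
    net.backward(dy)
    worst = 0.0
    for layer in net.layers:
        for name, p in layer.params.items():
            g = layer.grads[name]
            for _ in range(3):
                idx = tuple(rng.integers(s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss_value()
                p[idx] = old - eps
                lm = loss_value()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                denom = abs(num) + abs(g[idx]) + 1e-8
                worst = max(worst, abs(num - g[idx]) / denom)
    return worst


@pytest.mark.parametrize(
    "name,layers,shape",
    [
        ("dense_tanh", lambda: [Dense(7, activation="tanh"), Dense(2)], (5,)),
        ("dense_selu", lambda: [Dense(7, activation="selu"), Dense(2)], (5,)),
        ("dense_sigmoid", lambda: [Dense(7, activation="sigmoid"), Dense(2)], (5,)),
        (
            "conv_causal_dilated",
            lambda: [Conv1D(6, 3, dilation=2, activation="tanh"), TakeLast(), Dense(2)],
            (12, 4),
        ),
        (
            "conv_l1_relu",
            lambda: [Conv1D(5, 2, activation="relu", l1=1e-3), Flatten(), Dense(2)],
            (8, 3),
        ),
        (
            "stacked_lstm",
            lambda: [LSTM(6, return_sequences=True), LSTM(5), Dense(2)],
            (7, 3),
        ),
        (
            "flatten_repeat_lstm",
            lambda: [Flatten(), RepeatVector(1), LSTM(6), Dense(2)],
            (7, 3),
        ),
        (
            "nmda_gate",
            lambda: [NmdaGate(nmda_channel=2, x0=0.3, dx=0.2), Flatten(), Dense(2)],
            (6, 4),
        ),
        ("output_bias", lambda: [Dense(3), OutputBias()], (5,)),
    ],
)
def test_backward_matches_finite_differences(name, layers, shape):
    assert numeric_vs_analytic(layers(), shape) < 1e-4


def test_input_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    net = Sequential([Conv1D(4, 2, activation="tanh"), Flatten(), Dense(1)], (6, 3), seed=1)
    x = rng.normal(size=(2, 6, 3))
    y = rng.normal(size=(2, 1))
    out = net.forward(x)
    _, dy = mse(out, y)
    dx = net.backward(dy)
    eps = 1e-6
    idx = (0, 3, 1)
    xp = x.copy()
    xp[idx] += eps
    lp, _ = mse(net.forward(xp), y)
    xm = x.copy()
    xm[idx] -= eps
    lm, _ = mse(net.forward(xm), y)
    num = (lp - lm) / (2 * eps)
    assert dx[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_causality_of_dilated_convolution():
    net = Sequential([Conv1D(3, 2, dilation=2, activation=None)], (10, 2), seed=0)
    rng = np.random.default_rng(1)
    x = rng.normal(size=(1, 10, 2))
    base = net.forward(x)
    x2 = x.copy()
    x2[0, 7, :] += 1.0  # perturb a late sample
    out = net.forward(x2)
    assert np.allclose(out[0, :7], base[0, :7])
    assert not np.allclose(out[0, 7:], base[0, 7:])


def test_dropout_inactive_at_inference_and_masked_in_training():
    net = Sequential([Dense(16), Dropout(0.5)], (8,), seed=3)
    x = np.random.default_rng(0).normal(size=(4, 8))
    a = net.forward(x, training=False)
    b = net.forward(x, training=False)
    assert np.array_equal(a, b)
    c = net.forward(x, training=True)
    assert not np.array_equal(a, c)


class TestOptimizers:
    def _one_step(self, opt):
        p = {"w": np.array([10.0, -10.0])}
        g = {"w": np.array([300.0, 400.0])}  # norm 500, clipped to 1
        opt.step(p, g)
        return opt

    @pytest.mark.parametrize("opt_name", ["adam", "adam_nesterov", "adamax"])
    def test_global_norm_clipping(self, opt_name):
        opt = make_optimizer(opt_name, clipnorm=1.0)
        opt = self._one_step(opt)
        assert opt.last_grad_norm == pytest.approx(500.0)
        assert opt.last_applied_norm <= 1.0 + 1e-9

    def test_adam_converges_on_quadratic(self):
        opt = Adam(lr=0.1, clipnorm=10.0)
        p = {"w": np.array([5.0])}
        for _ in range(300):
            g = {"w": 2 * p["w"]}
            opt.step(p, g)
        assert abs(p["w"][0]) < 1e-2

    @pytest.mark.parametrize("cls", [Nadam, Adamax])
    def test_variants_also_descend(self, cls):
        opt = cls(lr=0.05, clipnorm=10.0)
        p = {"w": np.array([3.0])}
        for _ in range(400):
            opt.step(p, {"w": 2 * p["w"]})
        assert abs(p["w"][0]) < 0.05


def test_losses_and_gradients():
    pred = np.array([[1.0, 2.0]])
    target = np.array([[0.0, 4.0]])
    val, grad = mse(pred, target)
    assert val == pytest.approx((1 + 4) / 2)
    assert np.allclose(grad, np.array([[1.0, -2.0]]))
    val2, grad2 = mae(pred, target)
    assert val2 == pytest.approx(1.5)
    assert np.allclose(grad2, np.array([[0.5, -0.5]]))


def test_save_load_round_trip(tmp_path):
    net = Sequential(
        [Conv1D(4, 2, activation="relu"), Flatten(), Dense(3, activation="selu"), Dense(1)],
        (8, 3), seed=5,
    )
    x = np.random.default_rng(2).normal(size=(3, 8, 3))
    before = net.forward(x)
    net.save(tmp_path / "m")
    back = Sequential.load(tmp_path / "m")
    assert np.allclose(back.forward(x), before)
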