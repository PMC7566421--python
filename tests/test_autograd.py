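"""Finite-difference checks of the autodiff engine.

Every operator used by the models is verified against central
differences on small random inputs; if these pass, correctness of the
full network gradient follows from the chain rule.
"""

import numpy as np
import pytest

from fundusgru.nn import autograd as ag
from fundusgru.nn.layers import GRU, BatchNorm2D, Conv2D, Dense


RNG = np.random.default_rng(42)


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g


def check_op(build, x_data, rtol=5e-2, atol=5e-3):
    """Compare autodiff and numeric gradients of sum(op(x))."""
    x = ag.Tensor(x_data.copy(), requires_grad=True)
    out = build(x)
    out.sum().backward()
    analytic = x.grad.copy()

    holder = x.data  # numeric_grad perturbs this array in place

    def f():
        return float(build(ag.Tensor(holder)).data.sum())

    numeric = numeric_grad(f, holder)
    np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)


_C_FULL = ag.Tensor(RNG.normal(size=(4, 5)).astype(np.float32))
_C_ROW = ag.Tensor(RNG.normal(size=(1, 5)).astype(np.float32))
_C_MAT = ag.Tensor(RNG.normal(size=(5, 3)).astype(np.float32))


@pytest.mark.parametrize("op", [
    lambda x: x * _C_FULL,
    lambda x: x + _C_ROW,
    lambda x: ag.relu(x),
    lambda x: ag.sigmoid(x),
    lambda x: ag.tanh(x),
    lambda x: x.reshape(-1),
    lambda x: x.mean(axis=0),
    lambda x: x @ _C_MAT,
], ids=["mul", "add_broadcast", "relu", "sigmoid", "tanh", "reshape",
        "mean", "matmul"])
def test_elementwise_and_linear_grads(op):
    check_op(op, RNG.normal(size=(4, 5)).astype(np.float64))


@pytest.mark.parametrize("stride,padding", [(1, "same"), (2, "valid"), (2, "same")])
def test_conv2d_input_grad(stride, padding):
    w = ag.Tensor(RNG.normal(size=(3, 3, 2, 4)).astype(np.float32) * 0.3)
    check_op(lambda x: ag.conv2d(x, w, stride=stride, padding=padding),
             RNG.normal(size=(2, 7, 7, 2)).astype(np.float64))


def test_conv2d_weight_and_bias_grad():
    x = ag.Tensor(RNG.normal(size=(2, 6, 6, 2)).astype(np.float32))
    w = ag.Tensor(RNG.normal(size=(3, 3, 2, 3)).astype(np.float64) * 0.3,
                  requires_grad=True)
    b = ag.Tensor(np.zeros(3), requires_grad=True)
    ag.conv2d(x, w, b).sum().backward()
    aw, ab = w.grad.copy(), b.grad.copy()

    def f_w():
        return float(ag.conv2d(x, ag.Tensor(w.data), ag.Tensor(b.data)).data.sum())

    np.testing.assert_allclose(aw, numeric_grad(f_w, w.data), rtol=5e-2, atol=5e-3)
    # bias gradient of a sum is the output pixel count per channel
    np.testing.assert_allclose(ab, np.full(3, 2 * 6 * 6), rtol=1e-5)


def test_maxpool_grad_routes_to_argmax():
    check_op(lambda x: ag.maxpool2d(x, 2),
             RNG.normal(size=(2, 6, 6, 3)).astype(np.float64))


def test_avgpool_and_gap_grads():
    check_op(lambda x: ag.avgpool2d_same(x, 3),
             RNG.normal(size=(2, 5, 5, 2)).astype(np.float64))
    check_op(lambda x: ag.global_avg_pool(x),
             RNG.normal(size=(2, 4, 4, 3)).astype(np.float64))


def test_bce_with_logits_matches_manual_gradient():
    z = ag.Tensor(RNG.normal(size=6).astype(np.float32), requires_grad=True)
    y = (RNG.random(6) > 0.5).astype(float)
    loss = ag.bce_with_logits(z, y)
    loss.backward()
    p = 1 / (1 + np.exp(-z.data))
    np.testing.assert_allclose(z.grad, (p - y) / 6, rtol=1e-5, atol=1e-7)
    # value agrees with the clipped-log definition
    manual = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
    assert abs(float(loss.data) - manual) < 1e-6


def test_gru_gradient_flows_through_sequence():
    rng = np.random.default_rng(0)
    gru = GRU(3, 2, rng)

    def build(x):
        steps = [x * ag.Tensor(np.full((2, 3), c, np.float32))
                 for c in (1.0, 0.5, 0.25)]
        return gru(steps)

    check_op(build, rng.normal(size=(2, 3)).astype(np.float64))


def test_batchnorm_train_mode_gradient():
    rng = np.random.default_rng(1)
    bn = BatchNorm2D(2)
    bn.training = True
    scale = ag.Tensor(rng.normal(size=(2,)).astype(np.float32))

    def build(x):
        bn.running_mean[:] = 0  # keep running stats from drifting per call
        bn.running_var[:] = 1
        return bn(x) * scale

    check_op(build, rng.normal(size=(2, 3, 3, 2)).astype(np.float64))


def test_batchnorm_eval_uses_running_stats():
    bn = BatchNorm2D(1)
    bn.running_mean[:] = 2.0
    bn.running_var[:] = 4.0
    x = ag.Tensor(np.full((1, 2, 2, 1), 4.0, np.float32))
    out = bn(x)
    np.testing.assert_allclose(out.data, (4 - 2) / np.sqrt(4 + 1e-5), rtol=1e-4)


def test_backward_accumulates_over_shared_subexpression():
    x = ag.Tensor(np.array([1.0, 2.0]), requires_grad=True)
    y = x * x + x * 3.0
    y.sum().backward()
    np.testing.assert_allclose(x.grad, 2 * x.data + 3.0)
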