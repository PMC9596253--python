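"""Autodiff core: gradients against finite differences, optimiser algebra."""

import numpy as np
import pytest

from ctcascade.nn import core, layers
from ctcascade.nn.core import Tensor


def finite_difference_check(make_loss, param, rng, n_probe=15, eps=1e-2,
                            zero_first=()):
    """Max relative error between autodiff and central differences on the
    best-conditioned (largest-gradient) coordinates of ``param``.

    ``zero_first`` lists every tensor touched by the graph, whose stale
    gradients from a previous check must be cleared (grads accumulate)."""
    for p in zero_first:
        p.grad = None
    param.grad = None
    loss = make_loss()
    loss.backward()
    grad = param.grad.copy()
    flat = param.data.reshape(-1)
    errs = []
    for i in np.argsort(-np.abs(grad.reshape(-1)))[:min(n_probe, flat.size)]:
        orig = flat[i]
        flat[i] = orig + eps
        up = float(make_loss().data)
        flat[i] = orig - eps
        down = float(make_loss().data)
        flat[i] = orig
        fd = (up - down) / (2 * eps)
        g = grad.reshape(-1)[i]
        errs.append(abs(fd - g) / max(1e-4, abs(fd) + abs(g)))
    return max(errs)


def test_composite_network_gradients(rng):
    """conv -> relu -> pool -> upsample -> even-kernel conv -> CE, checked
    against central differences for input, weights and bias (float64 so
    the comparison is limited by truncation error, not precision)."""
    with core.default_dtype(np.float64):
        x = Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
        conv = layers.Conv2d(3, 4, 3, rng)
        conv2 = layers.Conv2d(4, 2, 2, rng)
        target = np.zeros((2, 8, 8), dtype=int)
        target[:, :4] = 1

        def make_loss():
            h = core.relu(conv(x))
            h = core.maxpool2x2(h)
            h = core.upsample2x(h)
            return core.softmax_cross_entropy(conv2(h), target)

        graph = (x, conv.weight, conv.bias, conv2.weight, conv2.bias)
        for param in graph[:4]:
            assert finite_difference_check(make_loss, param, rng, eps=1e-5,
                                           zero_first=graph) < 1e-4


def test_concat_add_slice_sigmoid_gradients(rng):
    with core.default_dtype(np.float64):
        x = Tensor(rng.normal(size=(1, 4, 4, 4)), requires_grad=True)
        t = rng.normal(size=(1, 2, 4, 4))
        mask = (rng.random((1, 2, 4, 4)) < 0.5).astype(float)

        def make_loss():
            both = core.concat_channels(core.slice_channels(x, 0, 2),
                                        core.sigmoid_t(core.slice_channels(x, 2, 4)))
            a = core.slice_channels(both, 0, 2)
            b = core.slice_channels(both, 2, 4)
            return core.masked_l2(core.add(a, b), t, mask)

        assert finite_difference_check(make_loss, x, rng, eps=1e-5) < 1e-4


def test_bce_pos_weight_value_and_gradient(rng):
    z = rng.normal(size=(3, 5)).astype(np.float32)
    t = (rng.random((3, 5)) < 0.3).astype(np.float32)
    pw = 7.0
    s = 1 / (1 + np.exp(-z.astype(np.float64)))
    expected = -(pw * t * np.log(s) + (1 - t) * np.log(1 - s)).mean()
    zt = Tensor(z, requires_grad=True)
    loss = core.bce_with_logits(zt, t, pos_weight=pw)
    assert float(loss.data) == pytest.approx(expected, rel=1e-5)
    loss.backward()
    expected_grad = (s * (1 + (pw - 1) * t) - pw * t) / z.size
    np.testing.assert_allclose(zt.grad, expected_grad, atol=1e-6)


def test_upsample_matrix_is_partition_of_unity():
    m = core._upsample_matrix(6)
    assert m.shape == (12, 6)
    np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-6)


def test_maxpool_routes_gradient_to_argmax():
    x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]), requires_grad=True)
    out = core.maxpool2x2(x)
    assert out.data.item() == 4.0
    loss = core.masked_l2(out, np.zeros((1, 1, 1, 1)), np.ones((1, 1, 1, 1)))
    loss.backward()
    np.testing.assert_array_equal(x.grad != 0,
                                  np.array([[[[False, False], [False, True]]]]))


class TestSGD:
    def test_vanilla_step(self, rng):
        p = Tensor(rng.normal(size=(4,)), requires_grad=True)
        g = rng.normal(size=(4,)).astype(np.float32)
        before = p.data.copy()
        p.grad = g.copy()
        layers.SGD([p], lr=0.1).step()
        np.testing.assert_allclose(p.data, before - 0.1 * g, atol=1e-7)

    def test_momentum_accumulates(self, rng):
        p = Tensor(np.zeros(3), requires_grad=True)
        g = np.ones(3, dtype=np.float32)
        opt = layers.SGD([p], lr=1.0, momentum=0.5)
        p.grad = g.copy(); opt.step()     # v = 1, p = -1
        p.grad = g.copy(); opt.step()     # v = 1.5, p = -2.5
        np.testing.assert_allclose(p.data, -2.5, atol=1e-6)

    def test_weight_decay_term(self):
        p = Tensor(np.array([2.0]), requires_grad=True)
        opt = layers.SGD([p], lr=0.1, weight_decay=0.5)
        p.grad = np.array([0.0], dtype=np.float32)
        opt.step()  # p -= 0.1 * (0 + 0.5 * 2) = 0.1
        np.testing.assert_allclose(p.data, [1.9], atol=1e-7)

    def test_invalid_hyperparameters(self):
        p = Tensor(np.zeros(1), requires_grad=True)
        with pytest.raises(ValueError):
            layers.SGD([p], lr=0.0)
        with pytest.raises(ValueError):
            layers.SGD([p], lr=0.1, momentum=1.0)
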