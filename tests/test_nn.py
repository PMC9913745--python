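"""Numeric gradient checks and contracts for the CNN engine."""

import numpy as np
import pytest

from wsiseg import nn


def numeric_grad(f, t, g, eps=1e-6):
    """Central finite differences of sum(f() * g) w.r.t. tensor t."""
    num = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = t.data[i]
        t.data[i] = orig + eps
        f1 = float((f().data * g).sum())
        t.data[i] = orig - eps
        f2 = float((f().data * g).sum())
        t.data[i] = orig
        num[i] = (f1 - f2) / (2 * eps)
    return num


def check_grads(f, tensors, rng, atol=1e-6):
    out = f()
    g = rng.normal(size=out.data.shape)
    out.backward(g)
    for t in tensors:
        np.testing.assert_allclose(t.grad, numeric_grad(f, t, g), atol=atol)


def f64_param(rng, shape):
    p = nn.Parameter(rng.normal(size=shape))
    p.data = p.data.astype(np.float64)
    return p


@pytest.mark.parametrize("stride,padding,groups,k,cin,cout", [
    (1, 1, 1, 3, 3, 4),
    (2, 1, 1, 3, 4, 6),
    (2, 2, 1, 5, 2, 4),
    (1, 2, 1, 5, 3, 3),
    (1, 1, 4, 3, 4, 4),     # depthwise
    (2, 1, 2, 3, 4, 6),     # grouped, strided
    (2, 3, 1, 7, 3, 4),     # resnet stem geometry
])
def test_conv2d_gradients(stride, padding, groups, k, cin, cout, rng):
    x = nn.Tensor(rng.normal(size=(2, cin, 8, 8)), requires_grad=True)
    w = f64_param(rng, (cout, cin // groups, k, k))
    b = f64_param(rng, (cout,))
    check_grads(lambda: nn.conv2d(x, w, b, stride, padding, groups),
                [x, w, b], rng)


def test_conv2d_channel_mismatch_rejected(rng):
    x = nn.Tensor(rng.normal(size=(1, 3, 8, 8)))
    w = f64_param(rng, (4, 2, 3, 3))
    with pytest.raises(ValueError, match="channels"):
        nn.conv2d(x, w)


@pytest.mark.parametrize("op", [nn.relu, nn.silu, nn.sigmoid,
                                nn.upsample_nearest2x, nn.global_avg_pool,
                                nn.avg_pool2d_3x3s1,
                                lambda x: nn.softmax(x, axis=1)])
def test_elementwise_and_pool_gradients(op, rng):
    x = nn.Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
    check_grads(lambda: op(x), [x], rng)


@pytest.mark.parametrize("kernel,stride,padding", [(2, 2, 0), (3, 2, 1)])
def test_max_pool_gradients(kernel, stride, padding, rng):
    # distinct values avoid argmax ties, where the subgradient is not unique
    vals = rng.permutation(2 * 2 * 8 * 8).astype(np.float64)
    x = nn.Tensor(vals.reshape(2, 2, 8, 8), requires_grad=True)
    check_grads(lambda: nn.max_pool2d(x, kernel, stride, padding), [x], rng)


def test_batch_norm_gradients(rng):
    x = nn.Tensor(rng.normal(size=(3, 4, 5, 5)), requires_grad=True)
    gamma = f64_param(rng, (4,))
    beta = f64_param(rng, (4,))
    rm, rv = np.zeros(4), np.ones(4)
    check_grads(lambda: nn.batch_norm2d(x, gamma, beta, rm.copy(), rv.copy(),
                                        training=True),
                [x, gamma, beta], rng, atol=1e-5)


def test_mul_broadcast_gradients(rng):
    x = nn.Tensor(rng.normal(size=(2, 4, 6, 6)), requires_grad=True)
    s = nn.Tensor(rng.normal(size=(2, 4, 1, 1)), requires_grad=True)
    check_grads(lambda: nn.mul(x, s), [x, s], rng)


def test_concat_gradients(rng):
    a = nn.Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
    b = nn.Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
    check_grads(lambda: nn.concat([a, b], axis=1), [a, b], rng)


class TestCrossEntropy:
    def test_gradient(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        labels = rng.integers(0, 3, (2, 4, 4))
        ignore = rng.random((2, 4, 4)) < 0.3
        check_grads(lambda: nn.softmax_cross_entropy(x, labels, ignore),
                    [x], rng)

    def test_ignored_pixels_contribute_zero_gradient(self, rng):
        """Masked pixels must have exactly zero gradient — equivalent to
        cropping them out of the loss."""
        x = nn.Tensor(rng.normal(size=(1, 3, 6, 6)), requires_grad=True)
        labels = rng.integers(0, 3, (1, 6, 6))
        ignore = np.zeros((1, 6, 6), bool)
        ignore[0, :3] = True
        loss = nn.softmax_cross_entropy(x, labels, ignore)
        loss.backward()
        assert (x.grad[0, :, :3, :] == 0).all()
        assert (x.grad[0, :, 3:, :] != 0).any()

    def test_all_ignored_rejected(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 3, 2, 2)))
        with pytest.raises(ValueError):
            nn.softmax_cross_entropy(x, np.zeros((1, 2, 2), int),
                                     np.ones((1, 2, 2), bool))

    def test_matches_manual_nll(self, rng):
        logits = rng.normal(size=(1, 3, 2, 2))
        labels = rng.integers(0, 3, (1, 2, 2))
        x = nn.Tensor(logits)
        loss = nn.softmax_cross_entropy(x, labels)
        # independent arithmetic
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        manual = -np.log([p[0, labels[0, i, j], i, j]
                          for i in range(2) for j in range(2)]).mean()
        assert float(loss.data) == pytest.approx(manual, rel=1e-9)


def test_soft_dice_loss_gradient(rng):
    x = nn.Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
    labels = rng.integers(0, 3, (1, 4, 4))
    check_grads(lambda: nn.soft_dice_loss(x, labels), [x], rng, atol=1e-5)


class TestModuleSystem:
    def test_seeded_init_is_deterministic(self):
        a = nn.Conv2d(3, 8, 3, rng=np.random.default_rng(5))
        b = nn.Conv2d(3, 8, 3, rng=np.random.default_rng(5))
        assert np.array_equal(a.weight.data, b.weight.data)

    def test_state_dict_round_trip(self, rng):
        m = nn.Sequential(nn.Conv2d(3, 4, 3, rng=rng),
                          nn.BatchNorm2d(4), nn.ReLU())
        state = m.state_dict()
        m2 = nn.Sequential(nn.Conv2d(3, 4, 3, rng=np.random.default_rng(9)),
                           nn.BatchNorm2d(4), nn.ReLU())
        m2.load_state_dict(state)
        x = np.random.default_rng(0).normal(size=(1, 3, 6, 6)).astype(
            np.float32)
        m.eval(), m2.eval()
        assert np.array_equal(m(nn.Tensor(x)).data, m2(nn.Tensor(x)).data)

    def test_frozen_params_skip_backward_and_optimiser(self, rng):
        conv = nn.Conv2d(2, 2, 3, rng=rng)
        conv.freeze()
        x = nn.Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        out = conv(x)
        assert not out.requires_grad     # frozen subgraph prunes the tape
        before = conv.weight.data.copy()
        opt = nn.Adam(conv.parameters())
        conv.weight.grad = np.ones_like(conv.weight.data)
        opt.step()
        assert np.array_equal(conv.weight.data, before)

    def test_adam_descends_on_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0], np.float32))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            p.grad = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-2
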