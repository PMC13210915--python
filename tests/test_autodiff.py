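"""Engine correctness: first-order gradients against finite differences,
second-order gradients through recorded backward passes, op semantics."""

import numpy as np
import pytest

from legeit import nn
from legeit.autodiff import Tensor, concat, no_grad


def numgrad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        o = x[i]
        x[i] = o + eps
        fp = f()
        x[i] = o - eps
        fm = f()
        x[i] = o
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_matches(build, params, tol=1e-6):
    out = build()
    for p in params:
        p.grad = None
    out.backward()
    for p in params:
        ana = p.grad.data if p.grad is not None else np.zeros(p.shape)
        num = numgrad(lambda: build().item(), p.data)
        scale = np.max(np.abs(num)) + 1e-12
        assert np.max(np.abs(ana - num)) / scale < tol, \
            f"gradient mismatch for param of shape {p.shape}"


@pytest.fixture
def x64(rng):
    return Tensor(rng.normal(0, 1, (2, 3, 6, 6)), requires_grad=True)


def test_elementwise_chain_gradients(rng):
    x = Tensor(rng.normal(0, 1, (4, 5)), requires_grad=True)
    w = Tensor(rng.normal(0, 1, (4, 5)))
    assert_grad_matches(
        lambda: ((x * w).sigmoid() + (x.abs() + 0.3).sqrt()
                 - x.leaky_relu(0.2) * 0.5).sum(), [x])


def test_matmul_broadcast_gradients(rng):
    a = Tensor(rng.normal(0, 1, (3, 4)), requires_grad=True)
    b = Tensor(rng.normal(0, 1, (2, 4, 5)), requires_grad=True)
    assert_grad_matches(lambda: (a.matmul(b)).tanh().sum(), [a, b])


def test_reduction_and_reshape_gradients(rng):
    x = Tensor(rng.normal(0, 1, (2, 3, 4)), requires_grad=True)
    assert_grad_matches(
        lambda: (x.mean(axis=(0, 2)) * x.sum(axis=1).mean()).sum(), [x])
    assert_grad_matches(
        lambda: x.transpose((2, 0, 1)).reshape(4, 6).max(axis=1).sum(), [x])


def test_concat_slice_gradients(rng):
    a = Tensor(rng.normal(0, 1, (2, 3)), requires_grad=True)
    b = Tensor(rng.normal(0, 1, (2, 2)), requires_grad=True)
    assert_grad_matches(
        lambda: concat([a, b], axis=1).slice_((slice(None), slice(1, 4)))
        .pow(2.0).sum(), [a, b])


def test_conv_gradients(rng, x64):
    conv = nn.Conv2d(3, 4, 3, stride=2, padding=1)
    conv.weight.data = conv.weight.data.astype(np.float64)
    conv.bias.data = conv.bias.data.astype(np.float64)
    assert_grad_matches(lambda: conv(x64).sigmoid().sum(),
                        [x64, conv.weight, conv.bias])


def test_grouped_dilated_conv_gradients(rng, x64):
    conv = nn.Conv2d(3, 3, 3, padding=2, dilation=2, groups=3)
    conv.weight.data = conv.weight.data.astype(np.float64)
    conv.bias.data = conv.bias.data.astype(np.float64)
    assert_grad_matches(lambda: conv(x64).pow(2.0).sum(),
                        [x64, conv.weight, conv.bias])


def test_conv_transpose_gradients(rng, x64):
    up = nn.ConvTranspose2d(3, 2)
    up.weight.data = up.weight.data.astype(np.float64)
    up.bias.data = up.bias.data.astype(np.float64)
    assert_grad_matches(lambda: up(x64).pow(2.0).sum(),
                        [x64, up.weight, up.bias])
    y = up(x64)
    assert y.shape == (2, 2, 12, 12)


def test_norm_layer_gradients(rng, x64):
    bn = nn.BatchNorm2d(3)
    bn.gamma.data = rng.normal(1, 0.1, 3)
    bn.beta.data = rng.normal(0, 0.1, 3)
    w = Tensor(rng.normal(0, 1, x64.shape))
    assert_grad_matches(lambda: (bn(x64).pow(2.0) * w).sum(),
                        [x64, bn.gamma, bn.beta], tol=1e-5)
    inorm = nn.InstanceNorm2d(3)
    assert_grad_matches(lambda: (inorm(x64).pow(2.0) * w).sum(), [x64],
                        tol=1e-5)


def test_maxpool_gradients(rng):
    x = Tensor(rng.normal(0, 1, (2, 2, 4, 4)), requires_grad=True)
    pool = nn.MaxPool2d(2)
    assert_grad_matches(lambda: pool(x).pow(2.0).sum(), [x])
    assert pool(x).shape == (2, 2, 2, 2)


def test_second_order_through_backward(rng):
    """d/dw of a function of (dL/dx) matches finite differences — the
    gradient-penalty pattern."""
    conv1 = nn.Conv2d(2, 3, 3, padding=1)
    conv2 = nn.Conv2d(3, 1, 3, padding=1)
    inorm = nn.InstanceNorm2d(3)
    for c in (conv1, conv2):
        c.weight.data = c.weight.data.astype(np.float64)
        c.bias.data = c.bias.data.astype(np.float64)
    x0 = rng.normal(0, 1, (2, 2, 8, 8))

    def gp():
        xi = Tensor(x0.copy(), requires_grad=True)
        out = conv2(inorm(conv1(xi)).leaky_relu(0.2))
        out.sum().backward(create_graph=True)
        g = xi.grad
        return (((g * g).sum(axis=(1, 2, 3)) + 1e-12).sqrt() - 1.0) \
            .pow(2.0).mean()

    val = gp()
    for w in (conv1.weight, conv2.weight):
        w.grad = None
    val.backward()
    ana1 = conv1.weight.grad.data.ravel()[:4].copy()
    ana2 = conv2.weight.grad.data.ravel()[:4].copy()
    for w, ana in [(conv1.weight, ana1), (conv2.weight, ana2)]:
        num = []
        for k in range(4):
            i = np.unravel_index(k, w.shape)
            o = w.data[i]
            w.data[i] = o + 1e-6
            fp = gp().item()
            w.data[i] = o - 1e-6
            fm = gp().item()
            w.data[i] = o
            num.append((fp - fm) / 2e-6)
        num = np.asarray(num)
        assert np.max(np.abs(ana - num)) / (np.max(np.abs(num)) + 1e-12) < 1e-5


def test_no_grad_blocks_graph(rng):
    x = Tensor(rng.normal(0, 1, (3, 3)), requires_grad=True)
    with no_grad():
        y = (x * 2).sum()
    assert not y.requires_grad
    y2 = (x * 2).sum()
    assert y2.requires_grad


def test_backward_accumulates_over_shared_nodes(rng):
    x = Tensor(rng.normal(0, 1, (3,)), requires_grad=True)
    y = x * 2
    z = (y * y + y).sum()
    z.backward()
    expected = 2 * (2 * 2 * x.data * 2 / 2) + 2  # d/dx (4x^2 + 2x) = 8x + 2
    assert np.allclose(x.grad.data, 8 * x.data + 2)


def test_adam_and_clipping(rng):
    p = nn.Parameter(np.ones(4))
    opt = nn.Adam([p], lr=0.1)
    loss = (Tensor(np.array([1.0, 2.0, 3.0, 4.0], np.float32)) * p).sum()
    loss.backward()
    norm = nn.clip_grad_norm_([p], 1.0)
    assert norm == pytest.approx(np.sqrt(30.0))
    assert nn.global_grad_norm([p]) <= 1.0 + 1e-6
    before = p.data.copy()
    opt.step()
    assert not np.allclose(p.data, before)
    assert opt.step_count == 1
    # lr=0 leaves parameters unchanged
    p2 = nn.Parameter(np.ones(4))
    opt2 = nn.Adam([p2], lr=0.0)
    (Tensor(np.ones(4, np.float32)) * p2).sum().backward()
    opt2.step()
    assert np.array_equal(p2.data, np.ones(4, np.float32))
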