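"""Architecture contracts: shapes, output range, recurrence, BAM behaviour,
parameter budgets, gradient flow."""

import numpy as np
import pytest

from legeit import nn
from legeit.autodiff import Tensor
from legeit.network import (BAM, BAMR2UNet, GeneratorConfig, PatchCritic,
                            RecurrentBlockBAM, resolution_config, count_macs,
                            LAPLACIAN_KERNEL)


@pytest.mark.parametrize("res", [32, 48, 64, 96])
def test_generator_shape_and_range(res, rng):
    gen = BAMR2UNet(GeneratorConfig(base_channels=8))
    x = Tensor(rng.normal(0, 3, (1, 1, res, res)).astype(np.float32))
    y = gen(x)
    assert y.shape == (1, 1, res, res)
    assert y.data.min() >= 0.0 and y.data.max() <= 2.0


def test_generator_rejects_bad_input(rng):
    gen = BAMR2UNet(GeneratorConfig(base_channels=8))
    with pytest.raises(ValueError):
        gen(Tensor(np.zeros((1, 2, 64, 64), np.float32)))
    with pytest.raises(ValueError):
        gen(Tensor(np.zeros((1, 1, 64, 48), np.float32)))


def test_parameter_budgets():
    """Generator ~12.6M (+-15%) at the reference width; critic ~2.8M."""
    gen = BAMR2UNet(GeneratorConfig(base_channels=32))
    n = gen.num_parameters()
    assert abs(n - 12.6e6) / 12.6e6 < 0.15
    critic = PatchCritic()
    assert abs(critic.num_parameters() - 2.8e6) / 2.8e6 < 0.15


def test_resolution_adapted_params_monotone():
    params = []
    macs = []
    for res in (32, 48, 64, 96):
        g = BAMR2UNet(resolution_config(res))
        params.append(g.num_parameters())
        macs.append(count_macs(g, res))
    assert params == sorted(params)
    assert macs == sorted(macs)
    assert all(p1 < p2 for p1, p2 in zip(params, params[1:]))


def test_recurrence_applies_conv1_t_times(rng):
    x = Tensor(rng.normal(0, 1, (2, 6, 8, 8)).astype(np.float32))
    for t in (1, 2, 3):
        blk = RecurrentBlockBAM(6, 6, t=t)
        blk(x)
        assert blk.conv1_calls == t
    with pytest.raises(ValueError):
        RecurrentBlockBAM(6, 6, t=0)


def test_recurrence_reinjects_input(rng):
    """With t=2 the second conv1 application acts on h0 + x (checked by
    direct re-composition)."""
    blk = RecurrentBlockBAM(4, 4, t=2, use_bam=False)
    blk.eval()   # freeze norm statistics to the identity-free eval path
    for m in blk.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.running_mean[:] = 0
            m.running_var[:] = 1
    x = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))

    def conv_bn_act(z):
        return blk.bn1(blk.conv1(z)).leaky_relu(0.2)

    h0 = conv_bn_act(x)
    h1 = conv_bn_act(h0 + x)
    expected = (blk.bn2(blk.conv2(h1)).leaky_relu(0.2)
                + blk.res_proj(x)).leaky_relu(0.2)
    got = blk(x)
    assert np.allclose(got.data, expected.data, atol=1e-6)


def test_recurrent_block_zero_conv1(rng):
    """Zeroed first conv collapses the recurrent chain; the block output
    reduces to the activated residual projection (plus conv2's constant
    response)."""
    blk = RecurrentBlockBAM(4, 4, t=2, use_bam=False)
    blk.eval()
    for m in blk.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.running_mean[:] = 0
            m.running_var[:] = 1
    blk.conv1.weight.data[:] = 0
    blk.conv1.bias.data[:] = 0
    blk.conv2.weight.data[:] = 0
    blk.conv2.bias.data[:] = 0
    x = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))
    got = blk(x)
    expected = blk.res_proj(x).leaky_relu(0.2)
    assert np.allclose(got.data, expected.data, atol=1e-6)


def test_bam_output_shape_and_maps(rng):
    bam = BAM(16)
    x = Tensor(rng.normal(0, 1, (2, 16, 12, 12)).astype(np.float32))
    out = bam(x)
    assert out.shape == x.shape
    ms = bam.spatial_map(x)
    mc = bam.channel_map(x)
    me = bam.edge_map(x)
    for m in (ms, mc, me):
        assert m.data.min() > 0.0 and m.data.max() < 1.0
    assert ms.shape == (2, 1, 12, 12)
    assert mc.shape == (2, 16, 1, 1)
    assert me.shape == x.shape


def test_bam_fusion_weights_initial_and_trainable():
    bam = BAM(8)
    assert bam.alpha.item() == pytest.approx(0.5)
    assert bam.beta.item() == pytest.approx(0.3)
    assert bam.gamma.item() == pytest.approx(0.2)
    pids = {id(p) for p in bam.parameters()}
    assert {id(bam.alpha), id(bam.beta), id(bam.gamma)} <= pids
    assert id(bam.e_conv.weight) in pids


def test_bam_degenerate_fusion_identity(rng):
    """alpha = gamma = 0 with identity normalization statistics leaves
    BAM(x) = beta * x exactly."""
    bam = BAM(8)
    bam.eval()
    bam.bn_out.running_mean[:] = 0
    bam.bn_out.running_var[:] = 1
    bam.bn_out.eps = 0.0
    bam.alpha.data = np.float32(0.0)
    bam.gamma.data = np.float32(0.0)
    x = Tensor(rng.normal(0, 1, (1, 8, 8, 8)).astype(np.float32))
    out = bam(x)
    assert np.allclose(out.data, 0.3 * x.data, atol=1e-6)


def test_bam_edge_branch_laplacian_init():
    """On a constant map the Laplacian response is 0 in the interior, so the
    thresholded edge map sits at sigmoid(0) = 0.5 there."""
    bam = BAM(4)
    assert np.allclose(bam.e_conv.weight.data[:, 0], LAPLACIAN_KERNEL)
    x = Tensor(np.full((1, 4, 16, 16), 0.7, np.float32))
    e = bam.e_conv(x).abs()
    assert np.allclose(e.data[:, :, 1:-1, 1:-1], 0.0, atol=1e-6)
    me = bam.edge_map(x)
    interior = me.data[:, :, 2:-2, 2:-2]
    # threshold = per-channel mean of |response|, small due to borders only
    thr = e.data.mean(axis=(2, 3))
    expect = 1.0 / (1.0 + np.exp(thr))  # sigmoid(0 - thr)
    assert np.allclose(interior, expect[..., None, None], atol=1e-5)


def test_critic_patch_map_and_channels(rng):
    d = PatchCritic()
    x = Tensor(rng.normal(0, 1, (2, 1, 64, 64)).astype(np.float32))
    y = Tensor(rng.normal(0, 1, (2, 1, 64, 64)).astype(np.float32))
    s = d(x, y)
    assert s.shape == (2, 1, 3, 3)
    assert [d.c1.out_ch, d.c2.out_ch, d.c3.out_ch, d.c4.out_ch,
            d.c5.out_ch] == [64, 128, 256, 512, 1]
    # conditional sensitivity: swapping target for condition changes scores
    s2 = d(x, x)
    assert not np.allclose(s.data, s2.data)
    with pytest.raises(ValueError):
        d(x, Tensor(np.zeros((2, 1, 32, 32), np.float32)))


def test_gradient_flow_to_all_parameters(rng):
    """Every trainable tensor, including the fusion scalars and the
    Laplacian kernels, receives a nonzero gradient on a random batch."""
    from legeit.training import initialize
    gen = BAMR2UNet(GeneratorConfig(base_channels=16))
    initialize(gen, PatchCritic(base_channels=8), seed=0)
    x = Tensor(rng.normal(0, 1, (2, 1, 32, 32)).astype(np.float32))
    t = Tensor(rng.random((2, 1, 32, 32)).astype(np.float32) * 2)
    out = gen(x)
    loss = ((out - t) * (out - t)).mean() + out.mean() * 0.1
    gen.zero_grad()
    loss.backward()
    missing = [n for n, p in gen.named_parameters()
               if p.grad is None or not np.any(p.grad.data != 0)]
    assert missing == [], f"no gradient reached: {missing[:8]}"


def test_bam_branch_toggles(rng):
    x = Tensor(rng.normal(0, 1, (1, 8, 8, 8)).astype(np.float32))
    for s, c, e in [(True, False, False), (False, True, False),
                    (False, False, True), (True, True, True)]:
        bam = BAM(8, spatial=s, channel=c, edge=e)
        assert bam(x).shape == x.shape
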