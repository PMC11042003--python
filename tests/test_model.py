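"""Network components against hand-looped oracles, plus shape algebra."""

import numpy as np
import pytest

from odcup.model import (CBAM, ChannelAttention, ModelConfig, ResCbamUNet,
                         ResidualBlock, SpatialAttention, as_batch,
                         load_checkpoint, save_checkpoint)
from odcup.nn import Tensor, no_grad
from odcup.nn import autograd as ag


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture
def rngm():
    return np.random.default_rng(31)


# ---------------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------------

def test_channel_attention_zero_weights_gives_half(rngm):
    att = ChannelAttention(8, reduction=2, rng=rngm)
    _zero_params(att)
    f = Tensor(rngm.normal(size=(1, 8, 4, 4)))
    out = att(f)
    np.testing.assert_allclose(out.data, 0.5)


def test_channel_attention_shape_and_range(rngm):
    att = ChannelAttention(8, reduction=16, rng=rngm)  # hidden clamps to 1
    out = att(Tensor(rngm.normal(size=(1, 8, 4, 4)))).data
    assert out.shape == (1, 8, 1, 1)
    assert np.all((out > 0) & (out < 1))


def test_channel_attention_matches_loop_oracle(rngm):
    c, h, w, hidden = 4, 3, 3, 2
    att = ChannelAttention(c, reduction=2, rng=rngm)
    f = rngm.normal(size=(1, c, h, w))
    out = att(Tensor(f)).data[0, :, 0, 0]

    w0, b0 = att.fc0.weight.data, att.fc0.bias.data
    w1, b1 = att.fc1.weight.data, att.fc1.bias.data
    # hand-looped: shared MLP over avg- and max-pooled descriptors
    avg = np.array([f[0, ci].mean() for ci in range(c)])
    mx = np.array([f[0, ci].max() for ci in range(c)])

    def mlp(v):
        hid = np.maximum(w0 @ v + b0, 0.0)
        return w1 @ hid + b1

    expected = _sigmoid(mlp(avg) + mlp(mx))
    np.testing.assert_allclose(out, expected, rtol=1e-5)


def test_channel_attention_spatial_permutation_invariant(rngm):
    att = ChannelAttention(6, reduction=2, rng=rngm)
    f = rngm.normal(size=(1, 6, 5, 5))
    perm = rngm.permutation(25)
    f_perm = f.reshape(1, 6, 25)[:, :, perm].reshape(1, 6, 5, 5)
    np.testing.assert_allclose(att(Tensor(f)).data, att(Tensor(f_perm)).data,
                               rtol=1e-6)


def test_channel_attention_rejects_empty(rngm):
    att = ChannelAttention(4, 2, rngm)
    with pytest.raises(ValueError):
        att(Tensor(np.zeros((1, 4, 0, 0))))


# ---------------------------------------------------------------------------
# spatial attention
# ---------------------------------------------------------------------------

def test_spatial_attention_zero_weights_gives_half(rngm):
    att = SpatialAttention(7, rngm)
    _zero_params(att)
    out = att(Tensor(rngm.normal(size=(1, 8, 5, 5))))
    np.testing.assert_allclose(out.data, 0.5)


def test_spatial_attention_shape(rngm):
    att = SpatialAttention(7, rngm)
    assert att(Tensor(rngm.normal(size=(1, 8, 5, 5)))).shape == (1, 1, 5, 5)


def test_spatial_attention_even_kernel_rejected(rngm):
    with pytest.raises(ValueError):
        SpatialAttention(4, rngm)
    with pytest.raises(ValueError):
        ModelConfig(spatial_kernel=6)


def test_spatial_attention_matches_loop_oracle(rngm):
    c, h, w, k = 3, 6, 6, 3
    att = SpatialAttention(k, rngm)
    f = rngm.normal(size=(1, c, h, w))
    out = att(Tensor(f)).data[0, 0]

    avg = f[0].mean(axis=0)
    mx = f[0].max(axis=0)
    stacked = np.stack([avg, mx])
    kw = att.conv.weight.data[0]
    bias = att.conv.bias.data[0]
    pad = k // 2
    sp = np.pad(stacked, ((0, 0), (pad, pad), (pad, pad)))
    expected = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            acc = bias
            for ch in range(2):
                for di in range(k):
                    for dj in range(k):
                        acc += sp[ch, i + di, j + dj] * kw[ch, di, dj]
            expected[i, j] = _sigmoid(acc)
    np.testing.assert_allclose(out, expected, rtol=1e-5)


def test_spatial_attention_channel_permutation_invariant(rngm):
    att = SpatialAttention(7, rngm)
    f = rngm.normal(size=(1, 8, 6, 6))
    perm = rngm.permutation(8)
    np.testing.assert_allclose(att(Tensor(f)).data, att(Tensor(f[:, perm])).data,
                               rtol=1e-6)


# ---------------------------------------------------------------------------
# CBAM
# ---------------------------------------------------------------------------

def test_cbam_zero_weights_quarters_input(rngm):
    cbam = CBAM(8, 2, 7, rngm)
    _zero_params(cbam)
    f = rngm.normal(size=(1, 8, 5, 5))
    np.testing.assert_allclose(cbam(Tensor(f)).data, 0.25 * f, rtol=1e-6)


def test_cbam_preserves_shape_and_composes(rngm):
    cbam = CBAM(8, 4, 7, rngm)
    f = rngm.normal(size=(2, 8, 6, 6))
    out = cbam(Tensor(f))
    assert out.shape == f.shape
    mc = cbam.channel(Tensor(f)).data
    f1 = f * mc
    ms = cbam.spatial(Tensor(f1)).data
    np.testing.assert_allclose(out.data, f1 * ms, rtol=1e-6)


def test_cbam_never_increases_magnitude(rngm):
    for trial in range(5):
        cbam = CBAM(8, 2, 7, np.random.default_rng(trial))
        f = np.random.default_rng(100 + trial).normal(size=(1, 8, 8, 8))
        out = cbam(Tensor(f)).data
        assert np.all(np.abs(out) <= np.abs(f) + 1e-12)


# ---------------------------------------------------------------------------
# residual block
# ---------------------------------------------------------------------------

def test_residual_block_identity_with_zero_weights(rngm):
    block = ResidualBlock(4, 4, rngm).eval()
    _zero_params(block)
    # restore the identity normalization (gamma back to 1)
    block.bn1.gamma.data[...] = 1.0
    block.bn2.gamma.data[...] = 1.0
    x = np.abs(rngm.normal(size=(1, 4, 6, 6)))
    out = block(Tensor(x)).data
    np.testing.assert_allclose(out, x, rtol=1e-4, atol=1e-5)


def test_residual_block_channel_doubling(rngm):
    block = ResidualBlock(8, 16, rngm)
    assert block.proj is not None
    out = block(Tensor(rngm.normal(size=(2, 8, 10, 10))))
    assert out.shape == (2, 16, 10, 10)
    same = ResidualBlock(8, 8, rngm)
    assert same.proj is None


def test_residual_block_matches_loop_oracle(rngm):
    """Eval-mode block against a straight NumPy re-computation."""
    block = ResidualBlock(2, 3, rngm, slope=0.01).eval()
    # randomize the BN statistics so the oracle exercises them
    for bn in (block.bn1, block.bn2, block.proj_bn):
        bn.running_mean[...] = rngm.normal(size=bn.running_mean.shape)
        bn.running_var[...] = rngm.uniform(0.5, 2.0, size=bn.running_var.shape)
    x = rngm.normal(size=(1, 2, 5, 5))

    def conv_loop(inp, weight, bias, pad):
        co, ci, k, _ = weight.shape
        h, w = inp.shape[1:]
        ip = np.pad(inp, ((0, 0), (pad, pad), (pad, pad)))
        out = np.empty((co, h + 2 * pad - k + 1, w + 2 * pad - k + 1))
        for o in range(co):
            for i in range(out.shape[1]):
                for j in range(out.shape[2]):
                    out[o, i, j] = bias[o] + np.sum(ip[:, i:i + k, j:j + k] * weight[o])
        return out

    def bn_eval(inp, bn):
        return bn.gamma.data[:, None, None] * (
            inp - bn.running_mean[:, None, None]
        ) / np.sqrt(bn.running_var[:, None, None] + bn.eps) + bn.beta.data[:, None, None]

    def lrelu(v):
        return np.where(v >= 0, v, 0.01 * v)

    h = lrelu(bn_eval(conv_loop(x[0], block.conv1.weight.data,
                                block.conv1.bias.data, 1), block.bn1))
    h = bn_eval(conv_loop(h, block.conv2.weight.data, block.conv2.bias.data, 1),
                block.bn2)
    sc = bn_eval(conv_loop(x[0], block.proj.weight.data, block.proj.bias.data, 0),
                 block.proj_bn)
    expected = lrelu(h + sc)
    np.testing.assert_allclose(block(Tensor(x)).data[0], expected, rtol=1e-5,
                               atol=1e-6)


# ---------------------------------------------------------------------------
# encoder / decoder / full model
# ---------------------------------------------------------------------------

def test_encoder_desk_scale_shapes(desk_cfg, rngm):
    model = ResCbamUNet(desk_cfg)
    x = Tensor(rngm.uniform(size=(1, 3, 64, 64)).astype(np.float32))
    with no_grad():
        bottleneck, skips = model.encoder(x)
    assert bottleneck.shape == (1, 128, 4, 4)
    assert [s.shape for s in skips] == [
        (1, 8, 64, 64), (1, 16, 32, 32), (1, 32, 16, 16), (1, 64, 8, 8)]
    assert np.isfinite(bottleneck.data).all()
    assert all(np.isfinite(s.data).all() for s in skips)


def test_encoder_rejects_wrong_side(desk_cfg, rngm):
    model = ResCbamUNet(desk_cfg)
    with pytest.raises(ValueError):
        model.encoder(Tensor(rngm.uniform(size=(1, 3, 48, 48))))
    with pytest.raises(ValueError):
        ModelConfig(input_side=100, depth=4)  # 100 not divisible by 16


def test_decoder_output_in_unit_interval(tiny_cfg, rngm):
    model = ResCbamUNet(tiny_cfg)
    x = Tensor(rngm.uniform(size=(2, 3, 32, 32)).astype(np.float32))
    with no_grad():
        out = model(x)
    assert out.shape == (2, 3, 32, 32)
    assert np.all((out.data > 0) & (out.data < 1))


def test_decoder_rejects_wrong_skip_count(tiny_cfg, rngm):
    model = ResCbamUNet(tiny_cfg)
    x = Tensor(rngm.uniform(size=(1, 3, 32, 32)).astype(np.float32))
    with no_grad():
        bottleneck, skips = model.encoder(x)
        with pytest.raises(ValueError):
            model.decoder(bottleneck, skips[:-1])


@pytest.mark.parametrize("base,depth,side", [(4, 2, 32), (8, 3, 48), (4, 4, 64)])
def test_shape_algebra_generalizes(base, depth, side, rngm):
    """Every stage obeys channels = base * 2^i, side = input / 2^i."""
    cfg = ModelConfig(input_side=side, base_channels=base, depth=depth, seed=0)
    model = ResCbamUNet(cfg)
    x = Tensor(rngm.uniform(size=(1, 3, side, side)).astype(np.float32))
    with no_grad():
        out, inter = model.forward_with_intermediates(x)
    for i in range(depth):
        assert inter[f"skip{i}"].shape == (1, base * 2 ** i, side // 2 ** i,
                                           side // 2 ** i)
    assert inter["bottleneck"].shape == (1, base * 2 ** depth, side // 2 ** depth,
                                         side // 2 ** depth)
    assert out.shape == (1, 3, side, side)


def test_model_forward_deterministic_in_eval_mode(tiny_cfg, rngm):
    model = ResCbamUNet(tiny_cfg).eval()
    x = Tensor(rngm.uniform(size=(1, 3, 32, 32)).astype(np.float32))
    with no_grad():
        a = model(x).data.copy()
        b = model(x).data.copy()
    assert np.array_equal(a, b)


def test_gradients_finite_at_init(tiny_cfg, rngm):
    model = ResCbamUNet(tiny_cfg)
    x = Tensor(rngm.uniform(size=(2, 3, 32, 32)).astype(np.float32))
    t = (rngm.uniform(size=(2, 3, 32, 32)) > 0.5).astype(np.float32)
    loss = ag.bce_loss_op(model(x), t)
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, name
        assert np.isfinite(p.grad).all(), name


def test_checkpoint_round_trip(tmp_path, tiny_cfg, rngm):
    model = ResCbamUNet(tiny_cfg).eval()
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, extra={"note": "test"})
    loaded = load_checkpoint(path).eval()
    assert loaded.cfg == tiny_cfg
    x = Tensor(rngm.uniform(size=(1, 3, 32, 32)).astype(np.float32))
    with no_grad():
        np.testing.assert_array_equal(model(x).data, loaded(x).data)


def test_checkpoint_rejects_inconsistent_state(tmp_path, tiny_cfg):
    model = ResCbamUNet(tiny_cfg)
    other = ResCbamUNet(ModelConfig(input_side=32, base_channels=8, depth=2, seed=0))
    with pytest.raises(ValueError):
        model.load_state_dict({k: v for k, v in list(other.state_dict().items())[:3]})


def test_as_batch_accepts_hwc_and_chw(rngm):
    hwc = rngm.uniform(size=(16, 16, 3))
    chw = hwc.transpose(2, 0, 1)
    np.testing.assert_array_equal(as_batch(hwc).data, as_batch(chw).data)
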