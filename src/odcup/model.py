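"""Residual-CBAM U-Net for joint optic-disc / optic-cup segmentation.

The encoder alternates feature stages with 3x3 max-pooling (stride 2,
padding 1) downsampling. The first stage is a plain 3x3 convolution taking
the RGB input to ``base_channels``; every later stage is a residual block
that doubles the channel count, and each stage is followed by a
convolutional block attention module (CBAM): serial channel attention
(shared two-layer perceptron over global average- and max-pooled
descriptors) and spatial attention (7x7 convolution over channel-pooled
average/max maps), each gating the features multiplicatively.

The decoder mirrors the encoder: a kernel-2 stride-2 transposed convolution
halves the channels and doubles the side, the matching encoder skip is
concatenated, and two 3x3 convolutions (each followed by batch
normalization and LeakyReLU) fuse the result. A final 1x1 convolution and
sigmoid produce three independent probability planes (background, disc,
cup) — a multilabel head, since every cup pixel is also a disc pixel.

With the default configuration (side 640, base 64, depth 4) the bottleneck
is 1024 x 40 x 40 and the output is 3 x 640 x 640.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_side`` must be divisible by ``2**depth`` so that pooling and
    transposed-convolution upsampling are exact inverses shape-wise.
    """

    input_side: int = 640
    in_channels: int = 3
    out_channels: int = 3
    base_channels: int = 64
    depth: int = 4
    cbam_reduction: int = 16
    spatial_kernel: int = 7
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.input_side < 1 or self.input_side % (2 ** self.depth) != 0:
            raise ValueError("input_side must be a positive multiple of 2**depth")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")
        for f in ("in_channels", "out_channels", "base_channels", "depth",
                  "cbam_reduction"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "ModelConfig":
        """A small configuration (side 64, base 8) for CPU-scale experiments.

        The attention reduction shrinks with the channel count (r = 4, so
        the shared MLP keeps a hidden width of at least 2 in every stage);
        with the full-scale r = 16 the first desk-scale stages would pass
        through a single hidden unit, which can die at initialization and
        occasionally collapses the cup channel during short trainings.
        """
        return cls(input_side=64, base_channels=8, cbam_reduction=4, seed=seed)

    def stage_channels(self, i: int) -> int:
        return self.base_channels * (2 ** i)


class ChannelAttention(nn.Module):
    """Channel gate: sigmoid(MLP(avgpool(F)) + MLP(maxpool(F))), shared MLP."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc0 = nn.Linear(channels, hidden, rng)
        self.fc1 = nn.Linear(hidden, channels, rng)

    def forward(self, f: Tensor) -> Tensor:
        if f.size == 0:
            raise ValueError("empty feature map")
        n, c = f.shape[0], f.shape[1]

        def mlp(v: Tensor) -> Tensor:
            return self.fc1(ag.relu(self.fc0(v)))

        avg = ag.reshape(ag.mean(f, (2, 3)), (n, c))
        mx = ag.reshape(ag.spatial_max(f), (n, c))
        gate = ag.sigmoid(ag.add(mlp(avg), mlp(mx)))
        return ag.reshape(gate, (n, c, 1, 1))


class SpatialAttention(nn.Module):
    """Spatial gate: sigmoid(conv_kxk([mean_c(F); max_c(F)]))."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        avg = ag.mean(f, (1,), keepdims=True)
        mx = ag.channel_max(f)
        return ag.sigmoid(self.conv(ag.concat([avg, mx], axis=1)))


class CBAM(nn.Module):
    """Serial channel-then-spatial attention; output keeps the input shape."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)

    def forward(self, f: Tensor) -> Tensor:
        f1 = ag.mul(f, self.channel(f))
        return ag.mul(f1, self.spatial(f1))


class ResidualBlock(nn.Module):
    """conv-norm-act-conv-norm + shortcut, activated after the addition.

    A 1x1 projection (with its own normalization) carries the identity path
    whenever the channel count changes, so the block can double channels
    while staying a near-identity at initialization.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 slope: float = 0.01):
        super().__init__()
        self.slope = slope
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, padding=0, rng=rng)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        h = ag.leaky_relu(self.bn1(self.conv1(x)), self.slope)
        h = self.bn2(self.conv2(h))
        sc = x if self.proj is None else self.proj_bn(self.proj(x))
        return ag.leaky_relu(ag.add(h, sc), self.slope)


class Encoder(nn.Module):
    """Feature-extraction path: stages of (block, CBAM) with pooled halving."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem = nn.Conv2d(cfg.in_channels, cfg.base_channels, 3, padding=1, rng=rng)
        blocks, cbams = [], []
        for i in range(1, cfg.depth + 1):
            blocks.append(ResidualBlock(cfg.stage_channels(i - 1), cfg.stage_channels(i),
                                        rng, cfg.leaky_slope))
            cbams.append(CBAM(cfg.stage_channels(i), cfg.cbam_reduction,
                              cfg.spatial_kernel, rng))
        self.stem_cbam = CBAM(cfg.base_channels, cfg.cbam_reduction,
                              cfg.spatial_kernel, rng)
        self.blocks = blocks
        self.cbams = cbams

    def forward(self, x: Tensor):
        cfg = self.cfg
        if x.shape[1] != cfg.in_channels or x.shape[2] != cfg.input_side \
                or x.shape[3] != cfg.input_side:
            raise ValueError(
                f"expected input {cfg.in_channels}x{cfg.input_side}x{cfg.input_side},"
                f" got {x.shape[1:]}"
            )
        skips = []
        h = self.stem_cbam(ag.leaky_relu(self.stem(x), cfg.leaky_slope))
        skips.append(h)
        for i in range(cfg.depth):
            h = ag.maxpool2d(h, kernel=3, stride=2, padding=1)
            h = self.cbams[i](self.blocks[i](h))
            if i < cfg.depth - 1:
                skips.append(h)
        return h, skips


class Decoder(nn.Module):
    """Feature fusion and restoration path with skip concatenation."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        ups, conv1s, bn1s, conv2s, bn2s = [], [], [], [], []
        for i in range(cfg.depth, 0, -1):
            hi, lo = cfg.stage_channels(i), cfg.stage_channels(i - 1)
            ups.append(nn.ConvTranspose2dX2(hi, lo, rng))
            conv1s.append(nn.Conv2d(hi, lo, 3, padding=1, rng=rng))
            bn1s.append(nn.BatchNorm2d(lo))
            conv2s.append(nn.Conv2d(lo, lo, 3, padding=1, rng=rng))
            bn2s.append(nn.BatchNorm2d(lo))
        self.ups, self.conv1s, self.bn1s = ups, conv1s, bn1s
        self.conv2s, self.bn2s = conv2s, bn2s
        self.head = nn.Conv2d(cfg.base_channels, cfg.out_channels, 1, padding=0, rng=rng)

    def forward(self, bottleneck: Tensor, skips: Sequence[Tensor]) -> Tensor:
        cfg = self.cfg
        if len(skips) != cfg.depth:
            raise ValueError(f"expected {cfg.depth} skip maps, got {len(skips)}")
        h = bottleneck
        for stage, skip in enumerate(reversed(list(skips))):
            h = self.ups[stage](h)
            if h.shape[1] != skip.shape[1] or h.shape[2:] != skip.shape[2:]:
                raise ValueError(
                    f"decoder stage {stage}: upsampled {h.shape[1:]} does not match"
                    f" skip {skip.shape[1:]}"
                )
            h = ag.concat([h, skip], axis=1)
            h = ag.leaky_relu(self.bn1s[stage](self.conv1s[stage](h)), cfg.leaky_slope)
            h = ag.leaky_relu(self.bn2s[stage](self.conv2s[stage](h)), cfg.leaky_slope)
        return ag.sigmoid(self.head(h))


class ResCbamUNet(nn.Module):
    """The full encoder-decoder network; parameters seeded from the config."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        bottleneck, skips = self.encoder(x)
        return self.decoder(bottleneck, skips)

    def forward_with_intermediates(self, x: Tensor):
        """Forward pass that also returns named intermediate feature maps."""
        bottleneck, skips = self.encoder(x)
        out = self.decoder(bottleneck, skips)
        inter = {f"skip{i}": s for i, s in enumerate(skips)}
        inter["bottleneck"] = bottleneck
        # replay the first decoder stage to expose its fused feature map
        h = self.decoder.ups[0](bottleneck)
        h = ag.concat([h, skips[-1]], axis=1)
        h = ag.leaky_relu(self.decoder.bn1s[0](self.decoder.conv1s[0](h)),
                          self.cfg.leaky_slope)
        h = ag.leaky_relu(self.decoder.bn2s[0](self.decoder.conv2s[0](h)),
                          self.cfg.leaky_slope)
        inter["decoder_stage0"] = h
        inter["output"] = out
        return out, inter


def as_batch(img: np.ndarray) -> Tensor:
    """Convert an (S, S, 3) or (3, S, S) image array to a 1x3xSxS tensor."""
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("expected a 3-d image array")
    if arr.shape[2] == 3 and arr.shape[0] != 3:
        arr = arr.transpose(2, 0, 1)
    return Tensor(arr[None])


def save_checkpoint(path, model: ResCbamUNet, extra: dict | None = None) -> None:
    """Serialize parameters + buffers with the config embedded as JSON."""
    meta = {"config": asdict(model.cfg)}
    if extra:
        meta["extra"] = extra
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.state_dict())


def load_checkpoint(path) -> ResCbamUNet:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    model = ResCbamUNet(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model
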