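"""Scene-aware fusion network (SAFNet) for 3D spine MRI segmentation.

The network reads a single-channel sagittal volume (B, 1, D, H, W) and emits
per-voxel class scores for every vertebra/disc structure plus background.
It is built from five stages:

1. **Feature extraction** — a CBR stem and residual blocks that keep the
   depth (sagittal-slice) axis untouched while halving height and width at
   each step, producing low- (D, H/4, W/4), mid- (D, H/8, W/8) and high-level
   (D, H/16, W/16) feature maps, all at ``base_channels`` channels.
2. **ASPP** — five parallel branches over the high-level features: a 1x1x1
   reduction, three 3x3x3 dilated convolutions (in-plane rates 6/12/18 with
   matching padding so resolution is preserved), and a global-pooling branch,
   concatenated and projected back to ``base_channels``.
3. **Self-attention** — a position-attention module (N x N affinity over the
   flattened voxel grid, queries/keys at C/8 channels) followed by a
   channel-attention module (C x C affinity); both add their output through a
   learnable scalar gate initialized to zero, so at initialization each
   module is an exact identity.
4. **Multiscale fusion** — four cascaded branches at C/4 channels with
   in-plane dilation rates 2/4/8/16; branch i adds branch i-1's output before
   its dilated convolution, and the four outputs concatenate back to C
   channels, enriching the low- and mid-level maps without losing resolution.
5. **Dimension splicing** — a channel gate (sigmoid of the global average of
   the attention-processed high-level features, itself channel-attended) is
   broadcast-multiplied with the fused low- and mid-level maps; the product,
   the two fused maps and the upsampled high-level map are concatenated and
   classified by a 1x1x1 convolution, then upsampled to the input grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    CBR,
    Adam,  # noqa: F401  (re-exported for convenience)
    Conv3d,
    Module,
    Parameter,
    Tensor,
    bmm,
    concat,
    conv_output_size,
    effective_kernel,
    no_grad,
    resize_linear,
)

__all__ = [
    "SAFNetConfig", "SAFNet", "ResidualBlock", "ASPP",
    "PositionAttention3D", "ChannelAttention3D", "MultiscaleFusion",
    "scene_gate", "conv_output_size", "effective_kernel",
]

#: Hard ceiling on N = D*H*W inside position attention; beyond this the
#: N x N affinity matrix is not worth materializing on a workstation.
MAX_ATTENTION_POSITIONS = 8192


@dataclass
class SAFNetConfig:
    """Architecture hyperparameters.

    ``num_classes`` counts background, so the nominal spine setting of 17
    labeled structures uses 18. ``base_channels`` must divide by 8 (the
    attention C/8 reduction) and 4 (the fusion C/4 reduction).
    """

    in_channels: int = 1
    base_channels: int = 128
    num_classes: int = 18
    aspp_dilations: tuple[int, ...] = (6, 12, 18)
    fusion_dilations: tuple[int, ...] = (2, 4, 8, 16)
    input_shape: tuple[int, int, int] = (18, 256, 128)

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.base_channels % 8 or self.base_channels % 4:
            raise ValueError("base_channels must be divisible by 8 and by 4")
        if self.input_shape[1] % 16 or self.input_shape[2] % 16:
            raise ValueError("input height and width must be divisible by 16")

    @classmethod
    def desk_scale(cls, num_classes: int = 6) -> "SAFNetConfig":
        """Reduced profile for CPU-scale experiments and tests."""
        return cls(base_channels=32, num_classes=num_classes,
                   input_shape=(12, 64, 32))


class ResidualBlock(Module):
    """Two-branch residual unit.

    The deep branch is two 3x3x3 CBR blocks (the first carrying the stride);
    the skip branch is a single 1x1x1 CBR with the same stride. The block
    output is the elementwise sum of the branches.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 stride=(1, 1, 1), rng: np.random.Generator | None = None):
        super().__init__()
        self.deep1 = CBR(in_channels, out_channels, 3, stride=stride,
                         padding=1, rng=rng)
        self.deep2 = CBR(out_channels, out_channels, 3, stride=1,
                         padding=1, rng=rng)
        self.skip = CBR(in_channels, out_channels, 1, stride=stride,
                        padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.deep2(self.deep1(x)) + self.skip(x)


class ASPP(Module):
    """Atrous spatial pyramid pooling with five branches.

    In-plane dilation rates come from the config (default 6/12/18) with
    padding equal to the rate, which keeps the spatial size unchanged; the
    depth axis uses rate 1. The pooling branch reduces to 1x1x1 by global
    averaging, passes a 1x1x1 convolution + ReLU (no batch norm: a single
    spatial location gives a degenerate batch statistic) and is broadcast
    back to the input grid.
    """

    def __init__(self, channels: int, dilations: tuple[int, ...],
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.reduce1x1 = CBR(channels, channels, 1, rng=rng)
        self.dilated = [
            CBR(channels, channels, 3, stride=1,
                padding=(1, d, d), dilation=(1, d, d), rng=rng)
            for d in dilations
        ]
        self.pool_conv = Conv3d(channels, channels, 1, rng=rng)
        n_branches = 2 + len(dilations)
        self.project = CBR(n_branches * channels, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        branches = [self.reduce1x1(x)]
        branches += [layer(x) for layer in self.dilated]
        pooled = self.pool_conv(x.mean(axis=(2, 3, 4), keepdims=True)).relu()
        ones = Tensor(np.ones((1, 1) + x.shape[2:], dtype=x.data.dtype))
        branches.append(pooled * ones)
        return self.project(concat(branches, axis=1))


class PositionAttention3D(Module):
    """Self-attention over flattened voxel positions (N = D*H*W).

    Query/key branches reduce to C/8 channels via 1x1x1 convolutions; the
    row-softmaxed N x N affinity reweights the value branch. The result is
    added to the input through a scalar gate initialized to 0, making the
    module an exact identity at initialization.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 8:
            raise ValueError("position attention requires channels divisible by 8")
        c8 = channels // 8
        self.query = Conv3d(channels, c8, 1, rng=rng)
        self.key = Conv3d(channels, c8, 1, rng=rng)
        self.value = Conv3d(channels, channels, 1, rng=rng)
        self.gate = Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        b, c, d, h, w = x.shape
        n = d * h * w
        if n > MAX_ATTENTION_POSITIONS:
            raise ValueError(
                f"position attention over N={n} positions would require an "
                f"{n}x{n} affinity matrix; feed a smaller feature map "
                f"(limit {MAX_ATTENTION_POSITIONS})")
        q = self.query(x).reshape(b, c // 8, n).transpose(0, 2, 1)  # (B,N,C/8)
        k = self.key(x).reshape(b, c // 8, n)                       # (B,C/8,N)
        attn = bmm(q, k).softmax(axis=2)                            # (B,N,N)
        v = self.value(x).reshape(b, c, n)                          # (B,C,N)
        out = bmm(v, attn.transpose(0, 2, 1)).reshape(b, c, d, h, w)
        return self.gate.reshape(1, 1, 1, 1, 1) * out + x

    def affinity(self, x: Tensor) -> Tensor:
        """Row-stochastic N x N position-affinity matrix (diagnostic)."""
        b, c, d, h, w = x.shape
        n = d * h * w
        q = self.query(x).reshape(b, c // 8, n).transpose(0, 2, 1)
        k = self.key(x).reshape(b, c // 8, n)
        return bmm(q, k).softmax(axis=2)


class ChannelAttention3D(Module):
    """Self-attention over channels via a row-softmaxed C x C affinity.

    Operates on the raw C channels (no reduction), with the same
    zero-initialized gated residual as the position module.
    """

    def __init__(self):
        super().__init__()
        self.gate = Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        n = int(np.prod(x.shape[2:]))
        xf = x.reshape(b, c, n)
        attn = bmm(xf, xf.transpose(0, 2, 1)).softmax(axis=2)  # (B,C,C)
        out = bmm(attn, xf).reshape(x.shape)
        return self.gate.reshape(1, 1, 1, 1, 1) * out + x

    def affinity(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        xf = x.reshape(b, c, int(np.prod(x.shape[2:])))
        return bmm(xf, xf.transpose(0, 2, 1)).softmax(axis=2)


class MultiscaleFusion(Module):
    """Four cascaded dilated branches enriching a feature map in place.

    Each branch reduces to C/4 channels (1x1x1 CBR) and applies a 3x3x3 CBR
    with in-plane dilation 2/4/8/16 (padding matched, resolution preserved).
    Branch i adds the previous branch's output before its dilated
    convolution; the four branch outputs concatenate back to C channels.
    """

    def __init__(self, channels: int, dilations: tuple[int, ...] = (2, 4, 8, 16),
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 4:
            raise ValueError("multiscale fusion requires channels divisible by 4")
        c4 = channels // 4
        self.reduces = [CBR(channels, c4, 1, rng=rng) for _ in dilations]
        self.convs = [
            CBR(c4, c4, 3, padding=(1, d, d), dilation=(1, d, d), rng=rng)
            for d in dilations
        ]

    def forward(self, x: Tensor) -> Tensor:
        outs: list[Tensor] = []
        prev: Tensor | None = None
        for reduce, conv in zip(self.reduces, self.convs):
            t = reduce(x)
            if prev is not None:
                t = t + prev
            prev = conv(t)
            outs.append(prev)
        return concat(outs, axis=1)


def scene_gate(f_h: Tensor) -> Tensor:
    """Channel response gate: sigmoid of the global spatial mean.

    Returns a (B, C, 1, 1, 1) tensor with every entry strictly in (0, 1).
    """
    return f_h.mean(axis=(2, 3, 4), keepdims=True).sigmoid()


class SAFNet(Module):
    """The full scene-aware fusion network."""

    def __init__(self, cfg: SAFNetConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg or SAFNetConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg.base_channels
        stem_c = max(c // 2, self.cfg.in_channels)

        # feature extraction: depth axis never strided anywhere
        self.stem = CBR(self.cfg.in_channels, stem_c, 3, stride=1, padding=1,
                        rng=rng)
        self.down = CBR(stem_c, c, 3, stride=(1, 2, 2), padding=1, rng=rng)
        self.res_low = ResidualBlock(c, c, stride=(1, 2, 2), rng=rng)
        self.res_mid = ResidualBlock(c, c, stride=(1, 2, 2), rng=rng)
        self.res_deep1 = ResidualBlock(c, c, stride=(1, 1, 1), rng=rng)
        self.res_deep2 = ResidualBlock(c, c, stride=(1, 1, 1), rng=rng)
        # three dilated CBR blocks; the first carries the final downsampling
        self.dilated = [
            CBR(c, c, 3, stride=(1, 2, 2), padding=(1, 2, 2),
                dilation=(1, 2, 2), rng=rng),
            CBR(c, c, 3, stride=1, padding=(1, 2, 2), dilation=(1, 2, 2),
                rng=rng),
            CBR(c, c, 3, stride=1, padding=(1, 4, 4), dilation=(1, 4, 4),
                rng=rng),
        ]

        self.aspp = ASPP(c, self.cfg.aspp_dilations, rng=rng)
        self.position_attention = PositionAttention3D(c, rng=rng)
        self.channel_attention = ChannelAttention3D()
        self.gate_attention = ChannelAttention3D()
        self.fusion_low = MultiscaleFusion(c, self.cfg.fusion_dilations, rng=rng)
        self.fusion_mid = MultiscaleFusion(c, self.cfg.fusion_dilations, rng=rng)
        self.classifier = Conv3d(4 * c, self.cfg.num_classes, 1, rng=rng)

    # -- stages ---------------------------------------------------------------
    def extract_features(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Return (low, mid, high) feature maps.

        Low level keeps the highest resolution (D, H/4, W/4); mid is
        (D, H/8, W/8); high is (D, H/16, W/16); all at base_channels.
        """
        x = self.down(self.stem(x))
        f_l = self.res_low(x)
        f_m = self.res_mid(f_l)
        y = self.res_deep2(self.res_deep1(f_m))
        for layer in self.dilated:
            y = layer(y)
        return f_l, f_m, y

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (B, {self.cfg.in_channels}, D, H, W), "
                f"got {x.shape}")
        in_spatial = x.shape[2:]

        f_l, f_m, f_h = self.extract_features(x)
        f_h = self.channel_attention(self.position_attention(self.aspp(f_h)))

        r_sam = self.gate_attention(scene_gate(f_h))         # (B,C,1,1,1)
        f_l2 = self.fusion_low(f_l)
        f_m2 = resize_linear(self.fusion_mid(f_m), f_l.shape[2:])
        f_sh = r_sam * f_l2 * f_m2
        f_h2 = resize_linear(f_h, f_l.shape[2:])

        fused = concat([f_sh, f_l2, f_m2, f_h2], axis=1)
        scores = self.classifier(fused)
        return resize_linear(scores, in_spatial)

    # -- inference helpers ----------------------------------------------------
    def predict_proba(self, x) -> np.ndarray:
        """Eval-mode per-voxel class probabilities (B, C, D, H, W)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                probs = self.forward(x).softmax(axis=1).numpy()
        finally:
            self.train(was_training)
        return probs

    def predict_labels(self, x) -> np.ndarray:
        """Eval-mode argmax label maps (B, D, H, W), values in [0, C)."""
        return np.argmax(self.predict_proba(x), axis=1)
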