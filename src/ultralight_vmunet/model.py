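"""UltraLight VM-UNet: a six-stage U-shaped segmentation network.

Encoder stages 1-3 are plain 3x3 convolution blocks (conv -> group norm ->
2x2 max pool -> ReLU); stages 4-6 are PVM layers.  The first five stage
outputs feed spatial- and channel-attention bridges (SAB/CAB) before being
added back as skips; stage 6 keeps the 1/32 resolution (no sixth pooling).
The decoder mirrors the encoder — three PVM stages then two convolution
stages, each followed by 2x bilinear upsampling (parameter-free, keeping the
budget ultra-light) — and a 1x1 convolution head produces a sigmoid
probability map at the input resolution.

With the default channel plan [8, 16, 24, 32, 48, 64] and quadruple-parallel
PVM stages the whole network has 49,454 trainable parameters (0.049M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as Fn
from .pvm import PVMLayer

__all__ = ["ModelConfig", "ConvBlock", "PVMStage", "SpatialAttentionBridge",
           "ChannelAttentionBridge", "UltraLightVMUNet", "build_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture switches.

    ``encoder_pvm``/``decoder_pvm`` swap the deep PVM stages for plain 3x3
    convolutions (component ablations); ``bridges`` toggles SAB+CAB.
    """

    channels: tuple = (8, 16, 24, 32, 48, 64)
    k: int = 4
    bridges: bool = True
    encoder_pvm: bool = True
    decoder_pvm: bool = True
    input_size: int = 256
    in_channels: int = 3
    out_channels: int = 1
    conv_mode: str = "depthwise"

    def __post_init__(self):
        if len(self.channels) != 6:
            raise ValueError("the channel plan must list 6 stage widths")
        if self.k not in (1, 2, 4):
            raise ValueError("k must be 1, 2 or 4")
        for c in self.channels[2:]:
            if c % self.k:
                raise ValueError(
                    f"deep-stage width {c} not divisible by k={self.k}")
        if self.input_size % 32 or self.input_size < 32:
            raise ValueError("input_size must be a positive multiple of 32")


def _to_tokens(x):
    B, C, H, W = x.shape
    return x.reshape(B, C, H * W).transpose(0, 2, 1), (H, W)


def _to_map(tokens, hw):
    H, W = hw
    B, _, C = tokens.shape
    return tokens.transpose(0, 2, 1).reshape(B, C, H, W)


class ConvBlock(nn.Module):
    """3x3 convolution at the stage's input resolution."""

    def __init__(self, in_c: int, out_c: int):
        self.conv = nn.Conv2d(in_c, out_c, 3, padding=1, bias=True)

    def forward(self, x):
        return self.conv(x)


class PVMStage(nn.Module):
    """A PVM layer applied to the flattened feature map."""

    def __init__(self, in_c: int, out_c: int, k: int, conv_mode: str):
        self.pvm = PVMLayer.create(in_c, out_c, k=k, conv_mode=conv_mode)

    def forward(self, x):
        tokens, hw = _to_tokens(x)
        return _to_map(self.pvm(tokens), hw)


class SpatialAttentionBridge(nn.Module):
    """Shared spatial gate over multi-stage skip features.

    Per stage: channelwise mean and max pooling -> a single 7x7 convolution
    shared by all stages -> sigmoid gate -> ``gate * x + x``.
    """

    def __init__(self):
        self.shared_conv = nn.Conv2d(2, 1, 7, padding=3, bias=True)

    def forward(self, features):
        out = []
        for t in features:
            pooled = nn.concat([t.mean(axis=1, keepdims=True),
                                t.amax(axis=1, keepdims=True)], axis=1)
            gate = self.shared_conv(pooled).sigmoid()
            out.append(t * gate + t)
        return out


class ChannelAttentionBridge(nn.Module):
    """Cross-stage channel gate: global average pooling per stage, the pooled
    vectors concatenated, one linear map per stage back to its width, sigmoid,
    channelwise scaling with a residual add."""

    def __init__(self, stage_channels):
        total = sum(stage_channels)
        self.atts = [nn.Linear(total, c, bias=True) for c in stage_channels]

    def forward(self, features):
        pooled = nn.concat([t.mean(axis=(2, 3)) for t in features], axis=1)
        out = []
        for att, t in zip(self.atts, features):
            gate = att(pooled).sigmoid()  # (B, C)
            B, C = gate.shape
            gate = gate.reshape(B, C, 1, 1)
            out.append(t * gate + t)
        return out


class UltraLightVMUNet(nn.Module):
    def __init__(self, cfg: ModelConfig = ModelConfig()):
        self.cfg = cfg
        c = cfg.channels

        def deep_stage(in_c, out_c, use_pvm):
            if use_pvm:
                return PVMStage(in_c, out_c, cfg.k, cfg.conv_mode)
            return ConvBlock(in_c, out_c)

        self.enc1 = ConvBlock(cfg.in_channels, c[0])
        self.enc2 = ConvBlock(c[0], c[1])
        self.enc3 = ConvBlock(c[1], c[2])
        self.enc4 = deep_stage(c[2], c[3], cfg.encoder_pvm)
        self.enc5 = deep_stage(c[3], c[4], cfg.encoder_pvm)
        self.enc6 = deep_stage(c[4], c[5], cfg.encoder_pvm)
        self.ebns = [nn.GroupNorm(4, ch) for ch in c[:5]]
        if cfg.bridges:
            self.sab = SpatialAttentionBridge()
            self.cab = ChannelAttentionBridge(c[:5])
        self.dec1 = deep_stage(c[5], c[4], cfg.decoder_pvm)
        self.dec2 = deep_stage(c[4], c[3], cfg.decoder_pvm)
        self.dec3 = deep_stage(c[3], c[2], cfg.decoder_pvm)
        self.dec4 = ConvBlock(c[2], c[1])
        self.dec5 = ConvBlock(c[1], c[0])
        self.dbns = [nn.GroupNorm(4, ch) for ch in (c[4], c[3], c[2], c[1], c[0])]
        self.head = nn.Conv2d(c[0], cfg.out_channels, 1, bias=True)

    def forward(self, x):
        """``(B, 3, S, S)`` image -> ``(B, 1, S, S)`` probability map."""
        x = nn.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, {self.cfg.in_channels}, S, S) input, got {x.shape}")
        S = x.shape[2]
        if x.shape[3] != S or S % 32 or S < 32:
            raise ValueError(
                f"input side must be a multiple of 32, got {x.shape[2:]}")
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite values in input image")

        skips = []
        out = x
        for enc, bn in zip((self.enc1, self.enc2, self.enc3, self.enc4, self.enc5),
                           self.ebns):
            out = Fn.max_pool2x2(bn(enc(out))).relu()
            skips.append(out)
        if self.cfg.bridges:
            skips = self.cab(self.sab(skips))
        out = self.enc6(out).relu()  # 1/32 resolution, no sixth pooling

        out = self.dbns[0](self.dec1(out)).relu() + skips[4]
        for dec, bn, skip in zip((self.dec2, self.dec3, self.dec4, self.dec5),
                                 self.dbns[1:], skips[3::-1]):
            out = Fn.upsample_bilinear_2x(bn(dec(out))).relu() + skip
        return Fn.upsample_bilinear_2x(self.head(out)).sigmoid()


def build_model(cfg: ModelConfig = ModelConfig(), seed=None) -> UltraLightVMUNet:
    """Construct a model, optionally reseeding parameter initialisation."""
    if seed is not None:
        nn.seed_all(seed)
    return UltraLightVMUNet(cfg)
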