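"""Dose-prediction network architectures.

Three variants, all mapping a multi-channel case stack (CT + structure
masks) to a single-channel 3D dose map on the same grid:

``hd``
    Hierarchically dense U-net: dense convolutions and dense downsampling
    in the encoder, dense convolutions in the decoder, plain skip
    concatenation. Feature counts grow linearly (growth rate per dense op)
    instead of doubling per level, which keeps the model small (3.4M
    parameters at the reference configuration).
``hda``
    The hd variant plus batch normalization after each convolution and
    additive attention gates on every skip connection (3.5M parameters at
    the reference configuration).
``attention``
    A standard 3D U-net with channel doubling per level and attention
    gates — the wide baseline (~26M parameters at base width 32).

In the decoder of the dense variants each stage is: trilinear upsampling to
the skip's grid, a 3x3x3 convolution compressing to ``ag_features``
channels (the gating signal; 64 in the reference configuration), the
attention gate on the skip (hda only), concatenation, then two dense
convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, maxpool3d_2x, resample_trilinear
from .nn import AttentionGate, BatchNorm3d, Conv3d, DenseConv, DenseDown, Module

__all__ = ["ArchConfig", "build_model", "count_parameters", "HDUNet", "AttentionUNet"]

VARIANTS = ("hd", "attention", "hda")


@dataclass
class ArchConfig:
    """Architecture variant and hyperparameters."""

    variant: str = "hda"
    in_channels: int = 21
    out_channels: int = 1
    levels: int = 5
    growth_rate: int = 16
    ag_features: int = 64
    base_features: int = 32  # attention variant only
    use_batch_norm: bool | None = None  # None -> True for hda, False otherwise

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if self.out_channels != 1:
            raise ValueError("dose prediction uses a single output channel")
        if self.use_batch_norm is None:
            self.use_batch_norm = self.variant == "hda"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "levels": self.levels,
            "growth_rate": self.growth_rate,
            "ag_features": self.ag_features,
            "base_features": self.base_features,
            "use_batch_norm": self.use_batch_norm,
        }


class HDUNet(Module):
    """Hierarchically dense U-net (``hd``) and its attention-gated variant
    (``hda``)."""

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        if cfg.variant not in ("hd", "hda"):
            raise ValueError("HDUNet builds the 'hd' or 'hda' variants")
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        g, bn = cfg.growth_rate, bool(cfg.use_batch_norm)
        gated = cfg.variant == "hda"

        c = cfg.in_channels
        self.enc_blocks: list[Module] = []
        self.down_blocks: list[Module] = []
        skip_channels: list[int] = []
        for _ in range(cfg.levels - 1):
            pair = []
            for _ in range(2):
                blk = DenseConv(c, g, batch_norm=bn, rng=rng, dtype=dtype)
                c = blk.out_channels
                pair.append(blk)
            self.enc_blocks.append(_Seq(pair))
            skip_channels.append(c)
            down = DenseDown(c, g, batch_norm=bn, rng=rng, dtype=dtype)
            c = down.out_channels
            self.down_blocks.append(down)
        bottom = []
        for _ in range(4):
            blk = DenseConv(c, g, batch_norm=bn, rng=rng, dtype=dtype)
            c = blk.out_channels
            bottom.append(blk)
        self.bottom = _Seq(bottom)

        self.up_convs: list[Module] = []
        self.up_bns: list[Module] = []
        self.gates: list[Module] = []
        self.dec_blocks: list[Module] = []
        u = cfg.ag_features
        for skip_c in reversed(skip_channels):
            self.up_convs.append(Conv3d(c, u, 3, rng=rng, dtype=dtype))
            if bn:
                self.up_bns.append(BatchNorm3d(u, dtype=dtype))
            if gated:
                self.gates.append(AttentionGate(skip_c, u, cfg.ag_features, rng=rng, dtype=dtype))
            c = skip_c + u
            pair = []
            for _ in range(2):
                blk = DenseConv(c, g, batch_norm=bn, rng=rng, dtype=dtype)
                c = blk.out_channels
                pair.append(blk)
            self.dec_blocks.append(_Seq(pair))
        self.head = Conv3d(c, cfg.out_channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        skips = []
        cur = x
        for enc, down in zip(self.enc_blocks, self.down_blocks):
            cur = enc(cur)
            skips.append(cur)
            cur = down(cur)
        cur = self.bottom(cur)
        for i, (upc, dec) in enumerate(zip(self.up_convs, self.dec_blocks)):
            skip = skips[-(i + 1)]
            cur = resample_trilinear(cur, skip.shape[1:])
            cur = upc(cur)
            if self.up_bns:
                cur = self.up_bns[i](cur)
            cur = cur.relu()
            if self.gates:
                skip = self.gates[i](skip, cur)
            cur = dec(concat([skip, cur], axis=0))
        return self.head(cur)


class AttentionUNet(Module):
    """Standard 3D U-net with channel doubling and attention-gated skips."""

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        widths = [cfg.base_features * 2**i for i in range(cfg.levels)]
        c = cfg.in_channels
        self.enc_blocks = []
        for f in widths[:-1]:
            self.enc_blocks.append(_Seq([_ConvRelu(c, f, rng, dtype), _ConvRelu(f, f, rng, dtype)]))
            c = f
        self.bottom = _Seq(
            [_ConvRelu(c, widths[-1], rng, dtype), _ConvRelu(widths[-1], widths[-1], rng, dtype)]
        )
        c = widths[-1]
        self.up_convs, self.gates, self.dec_blocks = [], [], []
        for f in reversed(widths[:-1]):
            self.up_convs.append(Conv3d(c, f, 3, rng=rng, dtype=dtype))
            self.gates.append(AttentionGate(f, f, cfg.ag_features, rng=rng, dtype=dtype))
            self.dec_blocks.append(
                _Seq([_ConvRelu(2 * f, f, rng, dtype), _ConvRelu(f, f, rng, dtype)])
            )
            c = f
        self.head = Conv3d(c, cfg.out_channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        cur = x
        for enc in self.enc_blocks:
            cur = enc(cur)
            skips.append(cur)
            cur = maxpool3d_2x(cur)
        cur = self.bottom(cur)
        for i, (upc, gate, dec) in enumerate(zip(self.up_convs, self.gates, self.dec_blocks)):
            skip = skips[-(i + 1)]
            cur = resample_trilinear(cur, skip.shape[1:])
            cur = upc(cur).relu()
            gated = gate(skip, cur)
            cur = dec(concat([gated, cur], axis=0))
        return self.head(cur)


class _Seq(Module):
    def __init__(self, blocks: list[Module]):
        super().__init__()
        self.blocks = list(blocks)

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return x


class _ConvRelu(Module):
    def __init__(self, c_in: int, c_out: int, rng, dtype):
        super().__init__()
        self.conv = Conv3d(c_in, c_out, 3, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()


def build_model(cfg: ArchConfig, seed: int | None = None, dtype=np.float64) -> Module:
    """Instantiate the configured variant with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    if cfg.variant in ("hd", "hda"):
        return HDUNet(cfg, rng=rng, dtype=dtype)
    return AttentionUNet(cfg, rng=rng, dtype=dtype)


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars in a model."""
    return int(sum(p.size for p in model.parameters()))
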