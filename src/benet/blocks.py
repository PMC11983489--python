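"""Boundary-aware building blocks: LCB, GMB and MSB.

* **LCB** (encoder): LoG-modulated 5x5 convolution -> BN/ReLU -> 3x3
  convolution -> BN/ReLU -> channel entropy attention.  Extracts
  second-derivative edge structure and keeps the channels whose pooled
  statistics are most salient.  The bottleneck variant carries a second 3x3
  convolution (``double=True``), mirroring the U-Net double-conv bottleneck.

* **GMB** (skip fusion): the encoder skip and the upsampled decoder map (C
  channels each) are concatenated to 2C channels and split evenly into four
  groups.  The two skip-derived groups see 3x3 convolutions at dilations 2
  and 3 (broad context for shallow features); the two decoder-derived groups
  see a 1x1 and a plain 3x3 (local detail for deep features).  Each group
  maps C/2 -> C so the four outputs can be summed, then ReLU and channel
  entropy attention.

* **MSB** (decoder refinement): a cascade of three 3x3 convolutions at
  dilations 1, 2, 3 whose per-stage outputs are summed (HMB), a sigmoid
  gate, the mean of stride-1 max pools at kernel sizes 3/5/7 multiplied by
  the gate (MPB weight W1), a per-pixel entropy weight map W2, and the
  residual combination ``(W1 + W2) * Y + Y``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor, concat, conv2d, maxpool2d
from .edge_operators import LoGConv2d
from .entropy_attention import apply_cea, sea_weights

__all__ = ["LCB", "GMB", "HMB", "MPB", "MSB"]


class LCB(nn.Module):
    """LoG-convolution boundary feature extraction block."""

    def __init__(self, in_channels: int, out_channels: int, sigma: float = 1.0,
                 zero_sum: bool = False, double: bool = False,
                 cea_residual: bool = False):
        super().__init__()
        if out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        self.logc = LoGConv2d(in_channels, out_channels, 5, sigma=sigma,
                              zero_sum=zero_sum)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv = nn.Conv2d(out_channels, out_channels, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(out_channels)
        self.extra = None
        if double:
            self.extra = nn.Sequential(
                nn.Conv2d(out_channels, out_channels, 3, padding=1),
                nn.BatchNorm2d(out_channels), nn.ReLU())
        self.cea_residual = cea_residual

    def forward(self, x, return_pre_cea: bool = False):
        y = self.bn1(self.logc(x)).relu()
        y = self.bn2(self.conv(y)).relu()
        if self.extra is not None:
            y = self.extra(y)
        out = apply_cea(y)
        if self.cea_residual:
            out = out + y
        if return_pre_cea:
            return out, y
        return out


class GMB(nn.Module):
    """Grouped multi-scale skip-fusion block.

    ``debug_identity=True`` replaces the four group convolutions by fixed
    1x1 channel-tiling maps (C/2 -> C, out channel j reads in channel
    j mod C/2), which makes the pre-attention output an exact ReLU of the
    sum of the lifted half-slices — used by the algebra tests.
    """

    def __init__(self, channels: int, cea_residual: bool = False,
                 debug_identity: bool = False):
        super().__init__()
        if channels < 2 or channels % 2:
            raise ValueError("GMB needs an even channel count >= 2 "
                             "(the 2C concatenation splits into 4 groups)")
        C, half = channels, channels // 2
        self.channels = C
        self.debug_identity = debug_identity
        if debug_identity:
            lift = np.zeros((C, half, 1, 1), dtype=nn.DTYPE)
            for o in range(C):
                lift[o, o % half, 0, 0] = 1.0
            self._lift = lift
        else:
            # group 1/2: skip halves, dilated 3x3; group 3/4: decoder halves
            self.conv1 = nn.Conv2d(half, C, 3, padding=2, dilation=2)
            self.conv2 = nn.Conv2d(half, C, 3, padding=3, dilation=3)
            self.conv3 = nn.Conv2d(half, C, 1)
            self.conv4 = nn.Conv2d(half, C, 3, padding=1)
            self.bns = [nn.BatchNorm2d(C) for _ in range(4)]
        self.cea_residual = cea_residual

    def forward(self, x_skip, x_decoder, return_pre_cea: bool = False):
        if x_skip.shape != x_decoder.shape:
            raise ValueError(
                f"skip/decoder shape mismatch: {x_skip.shape} vs "
                f"{x_decoder.shape}")
        if x_skip.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x_skip.shape[1]}")
        half = self.channels // 2
        cat = concat([x_skip, x_decoder], axis=1)     # 2C channels
        groups = [cat[:, i * half:(i + 1) * half] for i in range(4)]
        if self.debug_identity:
            maps = [conv2d(g, Tensor(self._lift)) for g in groups]
        else:
            convs = [self.conv1, self.conv2, self.conv3, self.conv4]
            maps = [bn(conv(g)) for g, conv, bn in zip(groups, convs, self.bns)]
        y = (maps[0] + maps[1] + maps[2] + maps[3]).relu()
        out = apply_cea(y)
        if self.cea_residual:
            out = out + y
        if return_pre_cea:
            return out, y
        return out


class HMB(nn.Module):
    """Hierarchical multi-scale cascade: 3x3 convs at dilations 1, 2, 3.

    Each stage consumes the previous stage's output; the three per-stage
    maps (after norm + activation) are summed.  ``literal_order=True``
    applies BN(ReLU(conv)) as printed; the default is the conventional
    conv -> BN -> ReLU.
    """

    def __init__(self, channels: int, literal_order: bool = False):
        super().__init__()
        self.convs = [nn.Conv2d(channels, channels, 3, padding=d, dilation=d)
                      for d in (1, 2, 3)]
        self.bns = [nn.BatchNorm2d(channels) for _ in range(3)]
        self.literal_order = literal_order

    def forward(self, x):
        stages = []
        cur = x
        for conv, bn in zip(self.convs, self.bns):
            if self.literal_order:
                cur = bn(conv(cur).relu())
            else:
                cur = bn(conv(cur)).relu()
            stages.append(cur)
        return stages[0] + stages[1] + stages[2]


def mpb_forward(y_prime) -> Tensor:
    """Multi-scale pooling weight W1 = y' * mean of max-pools (k = 3, 5, 7).

    All pools are stride 1 with symmetric padding k//2, so W1 has the shape
    of ``y_prime``.  The three pools are computed by nesting 3x3 max
    filters (a 5x5 max is a 3x3 max of a 3x3 max, identically so with the
    -inf border convention), which shares work across scales.
    """
    p3 = maxpool2d(y_prime, 3, stride=1, padding=1)
    p5 = maxpool2d(p3, 3, stride=1, padding=1)
    p7 = maxpool2d(p5, 3, stride=1, padding=1)
    avg = (p3 + p5 + p7) * (1.0 / 3.0)
    return y_prime * avg


class MPB(nn.Module):
    def forward(self, y_prime):
        return mpb_forward(y_prime)


class MSB(nn.Module):
    """Multi-scale spatial boundary block: HMB + MPB + spatial entropy weight.

    ``sea_from_sigmoid=True`` computes the entropy map W2 from the sigmoid
    output instead of the raw HMB sum (default: raw, matching the indexing
    of the entropy weight into the pre-sigmoid pyramid).
    """

    def __init__(self, channels: int, literal_order: bool = False,
                 sea_from_sigmoid: bool = False):
        super().__init__()
        if channels < 2:
            raise ValueError("MSB requires >= 2 channels (spatial entropy)")
        self.hmb = HMB(channels, literal_order=literal_order)
        self.sea_from_sigmoid = sea_from_sigmoid

    def forward(self, x):
        y = self.hmb(x)
        y_prime = y.sigmoid()
        w1 = mpb_forward(y_prime)
        w2 = sea_weights(y_prime if self.sea_from_sigmoid else y)
        return (w1 + w2) * y + y
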