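"""BE-Net encoder-decoder assembly, U-Net baselines, complexity accounting.

BE-Net is a quarter-width U-Net (stage widths 16/32/64/128/256 versus the
standard 64..1024) whose encoder double-convs are replaced by LCB blocks,
whose skip connections are fused by GMB blocks, and whose decoder levels are
refined by MSB blocks.  Input cubes are expected after PCA band reduction
(2 channels by default); the head is a 1x1 convolution to class logits.

Upsampling uses 3x3 stride-2 transposed convolutions and the bottleneck LCB
carries a second 3x3 convolution; with those choices the default model has
3,757,186 trainable parameters (3.757M) and the full-width U-Net baseline
34,524,610 (34.52M).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .blocks import GMB, LCB, MSB

__all__ = [
    "NetworkConfig",
    "ComplexityReport",
    "BENet",
    "UNet",
    "build_benet",
    "build_unet_baseline",
    "build_model",
    "complexity",
    "save_checkpoint",
    "load_checkpoint",
]

QUARTER_WIDTHS = (16, 32, 64, 128, 256)
FULL_WIDTHS = (64, 128, 256, 512, 1024)


@dataclass
class NetworkConfig:
    in_channels: int = 2
    num_classes: int = 2
    stage_widths: tuple = QUARTER_WIDTHS
    upsample_mode: str = "transposed"   # "transposed" | "bilinear" (reserved)
    sigma: float = 1.0
    zero_sum: bool = False
    lcb_first_level_only: bool = False
    hmb_literal_order: bool = False
    sea_from_sigmoid: bool = False
    cea_residual: bool = False

    def __post_init__(self):
        self.stage_widths = tuple(self.stage_widths)
        if len(self.stage_widths) != 5:
            raise ValueError("stage_widths must have exactly 5 levels")
        if any(b <= a for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            raise ValueError("stage_widths must be strictly increasing")


@dataclass
class ComplexityReport:
    n_params: int
    n_macs: int
    input_shape: tuple

    @property
    def n_flops(self) -> int:
        """FLOPs under the 2 x MACs convention."""
        return 2 * self.n_macs

    def to_dict(self):
        return {"n_params": self.n_params,
                "n_params_millions": round(self.n_params / 1e6, 3),
                "n_macs": self.n_macs, "n_flops_2xmacs": self.n_flops,
                "input_shape": list(self.input_shape)}


def _check_spatial(x):
    H, W = x.shape[2], x.shape[3]
    if H % 16 or W % 16:
        raise ValueError(
            f"input spatial size {H}x{W} must be divisible by 16 "
            "(four 2x2 downsamplings)")


class _DoubleConv(nn.Module):
    def __init__(self, cin, cout):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(cin, cout, 3, padding=1), nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, padding=1), nn.BatchNorm2d(cout), nn.ReLU())

    def forward(self, x):
        return self.block(x)


class BENet(nn.Module):
    """Boundary-aware entropy-weighted segmentation network."""

    def __init__(self, cfg: NetworkConfig | None = None):
        super().__init__()
        cfg = cfg or NetworkConfig()
        self.cfg = cfg
        w = cfg.stage_widths
        chans = [cfg.in_channels] + list(w)

        def enc_block(i, double=False):
            if cfg.lcb_first_level_only and i > 0:
                return _DoubleConv(chans[i], chans[i + 1])
            return LCB(chans[i], chans[i + 1], sigma=cfg.sigma,
                       zero_sum=cfg.zero_sum, double=double,
                       cea_residual=cfg.cea_residual)

        self.encoders = [enc_block(i) for i in range(4)]
        self.bottleneck = enc_block(4, double=True)
        self.pool = nn.MaxPool2d(2)
        self.ups = [nn.ConvTranspose2d(w[i + 1], w[i], 3, stride=2)
                    for i in reversed(range(4))]
        self.gmbs = [GMB(w[i], cea_residual=cfg.cea_residual)
                     for i in reversed(range(4))]
        self.msbs = [MSB(w[i], literal_order=cfg.hmb_literal_order,
                         sea_from_sigmoid=cfg.sea_from_sigmoid)
                     for i in reversed(range(4))]
        self.head = nn.Conv2d(w[0], cfg.num_classes, 1)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=nn.DTYPE))
        _check_spatial(x)
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, gmb, msb, skip in zip(self.ups, self.gmbs, self.msbs,
                                      reversed(skips)):
            x = up(x)
            x = gmb(skip, x)
            x = msb(x)
        return self.head(x)


class UNet(nn.Module):
    """Standard double-conv U-Net with 3x3 stride-2 transposed-conv upsampling."""

    def __init__(self, cfg: NetworkConfig | None = None):
        super().__init__()
        cfg = cfg or NetworkConfig(stage_widths=FULL_WIDTHS)
        self.cfg = cfg
        w = cfg.stage_widths
        chans = [cfg.in_channels] + list(w)
        self.encoders = [_DoubleConv(chans[i], chans[i + 1]) for i in range(4)]
        self.bottleneck = _DoubleConv(w[3], w[4])
        self.pool = nn.MaxPool2d(2)
        self.ups = [nn.ConvTranspose2d(w[i + 1], w[i], 3, stride=2)
                    for i in reversed(range(4))]
        self.decoders = [_DoubleConv(2 * w[i], w[i]) for i in reversed(range(4))]
        self.head = nn.Conv2d(w[0], cfg.num_classes, 1)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=nn.DTYPE))
        _check_spatial(x)
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = up(x)
            x = dec(concat([skip, x], axis=1))
        return self.head(x)


def build_benet(cfg: NetworkConfig | None = None, seed: int | None = None) -> BENet:
    if seed is not None:
        nn.seed_init(seed)
    return BENet(cfg)


def build_unet_baseline(cfg: NetworkConfig | None = None, quarter: bool = False,
                        seed: int | None = None) -> UNet:
    if seed is not None:
        nn.seed_init(seed)
    if cfg is None:
        cfg = NetworkConfig(
            stage_widths=QUARTER_WIDTHS if quarter else FULL_WIDTHS)
    return UNet(cfg)


def build_model(name: str, cfg: NetworkConfig | None = None,
                seed: int | None = None):
    name = name.lower()
    if name == "benet":
        return build_benet(cfg, seed)
    if name == "unet":
        return build_unet_baseline(cfg, quarter=False, seed=seed)
    if name in ("unet4", "unet_quarter"):
        return build_unet_baseline(cfg, quarter=True, seed=seed)
    raise ValueError(f"unknown model {name!r}")


def complexity(model: nn.Module,
               input_shape: tuple = (1, 2, 512, 512)) -> ComplexityReport:
    """Count trainable parameters and conv MACs for one forward pass.

    MACs count multiply-accumulates of (transposed) convolution layers; the
    common 'FLOPs' figure is reported as 2 x MACs (one multiply + one add).
    """
    n_params = model.num_parameters()
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros(input_shape, dtype=nn.DTYPE))
    with nn.count_macs() as counter:
        model(x)
        macs = counter.macs
    model.train(was_training)
    return ComplexityReport(n_params=n_params, n_macs=macs,
                            input_shape=tuple(input_shape))


CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: nn.Module, extra: dict | None = None):
    """Serialize model weights plus its config to a single .npz file."""
    path = Path(path)
    meta = {"version": CHECKPOINT_VERSION,
            "model_class": type(model).__name__,
            "config": asdict(model.cfg) if hasattr(model, "cfg") else None}
    if extra:
        meta["extra"] = {k: v for k, v in extra.items()
                         if not isinstance(v, np.ndarray)}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    if extra:
        arrays.update({f"extra/{k}": v for k, v in extra.items()
                       if isinstance(v, np.ndarray)})
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (model, meta) with weights restored."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        extra_arrays = {k[len("extra/"):]: data[k] for k in data.files
                        if k.startswith("extra/")}
    cfg = NetworkConfig(**meta["config"]) if meta.get("config") else None
    model = BENet(cfg) if meta["model_class"] == "BENet" else UNet(cfg)
    model.load_state_dict(state)
    meta["extra_arrays"] = extra_arrays
    return model, meta
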