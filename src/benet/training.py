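"""Training recipe, combined loss, segmentation metrics, cross-validation.

The recipe follows the original experimental protocol: SGD (momentum 0.9,
weight decay 1e-6), batch size 4, loss = 0.3 x pixelwise cross-entropy +
0.7 x soft Dice on the foreground probability, learning rate 0.01 (0.008 as
the alternative used on the smaller dataset), 80 epochs, five-fold
cross-validation with per-fold PCA fitted on training folds only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor
from .data import HyperCube, Mask, kfold_split, pca_reduce
from .network import NetworkConfig, build_benet, save_checkpoint, load_checkpoint

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "combined_loss",
    "compute_metrics",
    "to_arrays",
    "predict",
    "evaluate",
    "train",
    "cross_validate",
    "summarize_folds",
]

DICE_SMOOTH = 1e-5
METRIC_NAMES = ("oa", "dsc", "iou", "pre", "spe", "sen")


@dataclass
class TrainConfig:
    lr: float = 0.01                  # 0.008 is the small-dataset alternative
    momentum: float = 0.9
    weight_decay: float = 1e-6
    batch_size: int = 4
    epochs: int = 80
    w_ce: float = 0.3
    w_dice: float = 0.7
    seed: int = 0
    log_dir: str | None = None

    def __post_init__(self):
        if abs(self.w_ce + self.w_dice - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")
        for name in ("momentum", "weight_decay", "lr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class MetricsReport:
    """Confusion counts and the six derived ratios, all in [0, 1]."""

    tp: float
    fp: float
    fn: float
    tn: float
    oa: float
    dsc: float
    iou: float
    pre: float
    spe: float
    sen: float
    mode: str = "global"

    def as_dict(self):
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _ratio(num: float, den: float, both_empty: bool) -> float:
    """Undefined ratios: 1 when prediction and truth are both empty, else 0."""
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def _metrics_from_counts(tp, fp, fn, tn, mode) -> MetricsReport:
    both_empty = (tp + fp + fn) == 0
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        oa=_ratio(tp + tn, tp + fp + fn + tn, both_empty),
        dsc=_ratio(2 * tp, 2 * tp + fp + fn, both_empty),
        iou=_ratio(tp, tp + fp + fn, both_empty),
        pre=_ratio(tp, tp + fp, both_empty),
        spe=_ratio(tn, tn + fp, (tn + fp) == 0 and both_empty),
        sen=_ratio(tp, tp + fn, both_empty),
        mode=mode)


def compute_metrics(pred, target, mode: str = "global") -> MetricsReport:
    """Six-way segmentation metrics from binary masks.

    ``mode="global"`` pools the confusion counts over all pixels of all
    images (where DSC = 2 IoU / (1 + IoU) holds as an identity);
    ``mode="per_image"`` averages each metric over images.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    if not (np.isin(pred, (0, 1)).all() and np.isin(target, (0, 1)).all()):
        raise ValueError("masks must be binary {0, 1}")
    if pred.ndim == 2:
        pred, target = pred[None], target[None]
    pred = pred.astype(bool).reshape(pred.shape[0], -1)
    target = target.astype(bool).reshape(target.shape[0], -1)
    tp = (pred & target).sum(axis=1).astype(float)
    fp = (pred & ~target).sum(axis=1).astype(float)
    fn = (~pred & target).sum(axis=1).astype(float)
    tn = (~pred & ~target).sum(axis=1).astype(float)
    if mode == "global":
        return _metrics_from_counts(tp.sum(), fp.sum(), fn.sum(), tn.sum(),
                                    mode)
    if mode == "per_image":
        reports = [_metrics_from_counts(*counts, "per_image")
                   for counts in zip(tp, fp, fn, tn)]
        mean = {k: float(np.mean([getattr(r, k) for r in reports]))
                for k in METRIC_NAMES}
        return MetricsReport(tp=tp.sum(), fp=fp.sum(), fn=fn.sum(),
                             tn=tn.sum(), mode="per_image", **mean)
    raise ValueError(f"unknown mode {mode!r}")


def _log_softmax(logits: Tensor, axis: int = 1) -> Tensor:
    shifted = logits - logits.max(axis=axis, keepdims=True).detach()
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def combined_loss(logits: Tensor, target, w_ce: float = 0.3,
                  w_dice: float = 0.7) -> Tensor:
    """Weighted sum of 2-class softmax cross-entropy and soft Dice loss.

    ``logits`` is (B, 2, H, W); ``target`` is a (B, H, W) {0,1} array.  The
    Dice term is 1 minus the batch-mean soft Dice of the foreground
    probability, smoothed by 1e-5 in numerator and denominator.
    """
    target = np.asarray(target)
    if not np.isin(target, (0, 1)).all():
        raise ValueError("targets must be binary {0, 1}")
    if target.ndim == 2:
        target = target[None]
    B = logits.shape[0]
    logp = _log_softmax(logits, axis=1)
    onehot = np.stack([1.0 - target, target], axis=1).astype(logits.dtype)
    ce = -(logp * Tensor(onehot)).sum(axis=1).mean()
    p_fg = logp[:, 1].exp()
    t = Tensor(target.astype(logits.dtype))
    inter = (p_fg * t).sum(axis=(1, 2))
    denom = p_fg.sum(axis=(1, 2)) + t.sum(axis=(1, 2))
    dice = (inter * 2.0 + DICE_SMOOTH) / (denom + DICE_SMOOTH)
    return ce * w_ce + (1.0 - dice.mean()) * w_dice


def to_arrays(cubes: list[HyperCube], masks: list[Mask]):
    """Stack cubes/masks into (N, C, H, W) float32 and (N, H, W) uint8."""
    X = np.stack([np.moveaxis(c.values, 2, 0) for c in cubes]).astype(np.float32)
    Y = np.stack([m.labels for m in masks]).astype(np.uint8)
    return X, Y


def predict(model: nn.Module, X: np.ndarray, batch_size: int = 4) -> np.ndarray:
    """Argmax segmentation masks for a stack of (N, C, H, W) inputs."""
    model.eval()
    out = []
    for i in range(0, len(X), batch_size):
        logits = model(Tensor(X[i:i + batch_size]))
        out.append(logits.data.argmax(axis=1).astype(np.uint8))
    return np.concatenate(out)


def evaluate(model: nn.Module, X: np.ndarray, Y: np.ndarray,
             mode: str = "per_image", batch_size: int = 4) -> MetricsReport:
    return compute_metrics(predict(model, X, batch_size), Y, mode=mode)


def train(model: nn.Module, train_data, cfg: TrainConfig, val_data=None,
          ckpt_path=None, resume_from=None):
    """SGD training loop; returns a per-epoch history list.

    ``train_data``/``val_data`` are (X, Y) array pairs from
    :func:`to_arrays`.  Each epoch logs the mean loss (and validation DSC /
    IoU when a validation set is given) to ``cfg.log_dir/train_log.csv``;
    the best-validation-DSC weights are written to ``ckpt_path`` with
    optimizer and RNG state, so training can resume bit-exactly on the same
    hardware.
    """
    X, Y = train_data
    if len(X) == 0:
        raise ValueError("empty training set")
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    start_epoch = 0
    best_dsc = -1.0
    if resume_from is not None:
        model2, meta = load_checkpoint(resume_from)
        model.load_state_dict(model2.state_dict())
        extra = meta["extra_arrays"]
        opt.load_state_dict(
            {"velocity": [extra[f"vel_{i}"] for i in range(len(opt.velocity))]})
        rng.bit_generator.state = json.loads(meta["extra"]["rng_state"])
        start_epoch = int(meta["extra"]["epoch"]) + 1
        best_dsc = float(meta["extra"].get("best_dsc", -1.0))

    log_rows = []
    history = []
    for epoch in range(start_epoch, cfg.epochs):
        model.train()
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model(Tensor(X[idx]))
            loss = combined_loss(logits, Y[idx], cfg.w_ce, cfg.w_dice)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {i // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_data is not None:
            rep = evaluate(model, *val_data)
            entry["val_dsc"] = rep.dsc
            entry["val_iou"] = rep.iou
            if rep.dsc > best_dsc:
                best_dsc = rep.dsc
                if ckpt_path is not None:
                    _save_train_ckpt(Path(ckpt_path).with_suffix(".best.npz"),
                                     model, opt, rng, epoch, best_dsc)
        history.append(entry)
        log_rows.append(entry)
        if ckpt_path is not None:
            _save_train_ckpt(ckpt_path, model, opt, rng, epoch, best_dsc)
    if cfg.log_dir is not None:
        log_dir = Path(cfg.log_dir)
        log_dir.mkdir(parents=True, exist_ok=True)
        keys = ["epoch", "loss"] + (["val_dsc", "val_iou"]
                                    if val_data is not None else [])
        with open(log_dir / "train_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(log_rows)
        (log_dir / "train_config.json").write_text(json.dumps(asdict(cfg)))
    return history


def _save_train_ckpt(path, model, opt, rng, epoch, best_dsc):
    extra = {f"vel_{i}": v for i, v in enumerate(opt.velocity)}
    extra["rng_state"] = json.dumps(rng.bit_generator.state)
    extra["epoch"] = epoch
    extra["best_dsc"] = best_dsc
    save_checkpoint(path, model, extra=extra)


def cross_validate(cubes, masks, cfg: TrainConfig, k: int = 5,
                   n_components: int = 2,
                   net_cfg: NetworkConfig | None = None,
                   model_builder=None, mode: str = "per_image"):
    """k-fold cross-validation with train-fold-only PCA fitting.

    Returns (per-fold MetricsReport list, summary dict of mean/std per
    metric).  ``model_builder(seed) -> model`` defaults to BE-Net with
    ``net_cfg``.
    """
    split = kfold_split(len(cubes), k, seed=cfg.seed)
    reports = []
    for fold in range(k):
        tr, va = split.train_val(fold)
        reduced = pca_reduce(cubes, n_components, fit_indices=tr)
        Xtr, Ytr = to_arrays([reduced[i] for i in tr],
                             [masks[i] for i in tr])
        Xva, Yva = to_arrays([reduced[i] for i in va],
                             [masks[i] for i in va])
        if model_builder is not None:
            model = model_builder(cfg.seed + fold)
        else:
            model = build_benet(net_cfg, seed=cfg.seed + fold)
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + fold,
                                  "log_dir": None})
        train(model, (Xtr, Ytr), fold_cfg, val_data=(Xva, Yva))
        reports.append(evaluate(model, Xva, Yva, mode=mode))
    return reports, summarize_folds(reports)


def summarize_folds(reports: list[MetricsReport]) -> dict:
    """Mean and standard deviation of each metric across folds."""
    out = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        out[name] = {"mean": float(np.mean(vals)), "std": float(np.std(vals))}
    return out
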