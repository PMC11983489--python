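"""Information-entropy attention primitives.

Two complementary weightings, both parameter-free:

* **Channel entropy attention (CEA).**  For each channel, the global max-pool
  and global average-pool values are softmaxed into a two-element probability
  distribution whose Shannon entropy H is compared with its maximum log 2.
  The channel weight is ``W_c = 1 - H / log 2``: a spatially constant channel
  (max == mean) gets weight 0, a channel with a large max-mean gap gets a
  weight approaching 1.  Low pooled-pair entropy is read as a sharp, salient
  channel worth keeping.

* **Spatial entropy attention (SEA).**  At each pixel, the C channel values
  are softmaxed and their entropy is normalised by log C, giving
  ``W = H / log C`` in [0, 1].  Pixels whose channel responses are uniform
  (high uncertainty, typically boundary regions) receive weight 1; pixels
  dominated by a single channel receive weights near 0.

The entropy base cancels in both ratios, so natural logs are used
throughout.  Probabilities are clamped at 1e-12 inside p*log(p) to keep the
0*log(0) limit exact.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concat

__all__ = [
    "softmax_entropy",
    "cea_weights",
    "apply_cea",
    "sea_weights",
    "apply_sea",
]

_EPS = 1e-12


def _entropy_along(x: Tensor, axis: int) -> Tensor:
    """Shannon entropy (nats) of softmax(x) along `axis`, differentiably."""
    shifted = x - x.max(axis=axis, keepdims=True).detach()
    e = shifted.exp()
    p = e / e.sum(axis=axis, keepdims=True)
    return -(p * p.clamp_min(_EPS).log()).sum(axis=axis)


def softmax_entropy(values) -> float:
    """Entropy (nats) of the softmax distribution of a 1-D value vector."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("softmax_entropy expects a 1-D vector of length >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("softmax_entropy requires finite values")
    return float(_entropy_along(Tensor(arr), axis=0).item())


def cea_weights(x) -> Tensor:
    """Per-channel entropy weights ``1 - H(softmax(max, mean)) / log 2``.

    Input is a (B, C, H, W) tensor; output has shape (B, C), every entry in
    [0, 1].  Each batch item is treated independently.
    """
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValueError("expected a (B, C, H, W) feature map")
    B, C = x.shape[:2]
    x_gm = x.max(axis=(2, 3)).reshape(B, C, 1)
    x_ga = x.mean(axis=(2, 3)).reshape(B, C, 1)
    x_g = concat([x_gm, x_ga], axis=2)          # (B, C, 2)
    h = _entropy_along(x_g, axis=2)             # (B, C)
    return 1.0 - h * (1.0 / np.log(2.0))


def apply_cea(x) -> Tensor:
    """Reweight each channel of x by its entropy weight (pure multiplication)."""
    x = as_tensor(x)
    w = cea_weights(x)
    B, C = x.shape[:2]
    return x * w.reshape(B, C, 1, 1)


def sea_weights(x) -> Tensor:
    """Per-pixel entropy weights ``H(softmax over channels) / log C``.

    Input is a (B, C, H, W) tensor with C >= 2; output has shape
    (B, 1, H, W), every entry in [0, 1].  Pixels whose channel vector is
    constant receive weight exactly 1.
    """
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValueError("expected a (B, C, H, W) feature map")
    C = x.shape[1]
    if C < 2:
        raise ValueError("spatial entropy attention requires C >= 2 channels")
    h = _entropy_along(x, axis=1)               # (B, H, W)
    w = h * (1.0 / np.log(C))
    B, H, W = w.shape
    return w.reshape(B, 1, H, W)


def apply_sea(x) -> Tensor:
    """Multiply x by its spatial entropy weight map (broadcast over channels)."""
    x = as_tensor(x)
    return x * sea_weights(x)
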