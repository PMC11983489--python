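"""Shared fixtures and independent scalar-loop oracles.

The oracle implementations here deliberately use plain Python loops and
textbook formulas so they share no code path with the vectorised package
implementations they check.
"""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def entropy_of(values):
    """Shannon entropy (nats) of softmax(values), scalar arithmetic."""
    v = np.asarray(values, dtype=float)
    e = np.exp(v - v.max())
    p = e / e.sum()
    return -sum(pi * np.log(pi) for pi in p if pi > 0)


def cea_weights_oracle(x):
    """Channel weights 1 - H(softmax(max, mean)) / log 2, looped per channel."""
    B, C = x.shape[:2]
    out = np.zeros((B, C))
    for b in range(B):
        for c in range(C):
            pooled = [x[b, c].max(), x[b, c].mean()]
            out[b, c] = 1.0 - entropy_of(pooled) / np.log(2.0)
    return out


def sea_weights_oracle(x):
    """Pixel weights H(softmax over channels) / log C, looped per pixel."""
    B, C, H, W = x.shape
    out = np.zeros((B, H, W))
    for b in range(B):
        for i in range(H):
            for j in range(W):
                out[b, i, j] = entropy_of(x[b, :, i, j]) / np.log(C)
    return out


def conv2d_oracle(x, w, bias=None, padding=0, dilation=1):
    """Direct-sum 2-D cross-correlation for a single image (C,H,W)."""
    C, H, W = x.shape
    O, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    Ho = H + 2 * padding - dilation * (k - 1)
    Wo = W + 2 * padding - dilation * (k - 1)
    y = np.zeros((O, Ho, Wo))
    for o in range(O):
        for i in range(Ho):
            for j in range(Wo):
                acc = 0.0
                for c in range(C):
                    for u in range(k):
                        for v in range(k):
                            acc += (w[o, c, u, v]
                                    * xp[c, i + u * dilation, j + v * dilation])
                y[o, i, j] = acc + (bias[o] if bias is not None else 0.0)
    return y


def maxpool_same_oracle(x, k):
    """Stride-1 k x k max pool with -inf border, looped per pixel."""
    C, H, W = x.shape
    h = k // 2
    y = np.full_like(x, -np.inf)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                lo_i, hi_i = max(0, i - h), min(H, i + h + 1)
                lo_j, hi_j = max(0, j - h), min(W, j + h + 1)
                y[c, i, j] = x[c, lo_i:hi_i, lo_j:hi_j].max()
    return y
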