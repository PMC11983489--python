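"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains its segmentation networks on CPU with plain numpy, so the
graph machinery here is deliberately small: a :class:`Tensor` wrapping an
``ndarray``, a handful of differentiable primitives (elementwise arithmetic,
reductions, matmul, stride-1 dilated convolution via im2col, max pooling,
zero-stuffing for transposed convolution), and topological-order
backpropagation.  Convolutions are stride-1 only; spatial down/upsampling is
expressed through pooling and zero-stuffed convolution, which is all the
networks need.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "zero_stuff2d",
    "flip_swap_io",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._parents = _parents

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------
    def _accumulate(self, g, fresh: bool = False):
        """Add `g` into the gradient; `fresh=True` promises `g` is a newly
        allocated array no other node holds, so it can be adopted directly."""
        if self.grad is None:
            if fresh and isinstance(g, np.ndarray) and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # the graph is single-use: break closure cycles and free activations
        for node in topo:
            node._backward = None
            node._parents = ()
            if node is not self and not node.requires_grad:
                node.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (g / b.data, -g * a.data / (b.data ** 2)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bw(g, a=self, p=p):
            if a.requires_grad:
                a._accumulate(g * p * (a.data ** (p - 1)))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[idx] = g
                a._accumulate(full)

        out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw(g, a=self):
            if a.requires_grad:
                a._accumulate(g.reshape(a.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        """Max reduction; the gradient is split evenly among tied maxima."""
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims or axis is None else np.squeeze(m, axis)
        if axis is None and not keepdims:
            out_data = self.data.max()
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g, a=self, axis=axis, keepdims=keepdims, m=m):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            elif axis is None:
                g = np.asarray(g).reshape((1,) * a.data.ndim)
            mask = (a.data == m)
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None \
                else mask.sum()
            a._accumulate(mask * (g / counts))

        out._backward = bw
        return out

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        ex = np.exp(self.data)
        out = Tensor(ex, self.requires_grad, (self,))

        def bw(g, a=self, ex=ex):
            if a.requires_grad:
                a._accumulate(g * ex)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def bw(g, a=self):
            if a.requires_grad:
                a._accumulate(g * (a.data > 0))

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def bw(g, a=self, s=s):
            if a.requires_grad:
                a._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def clamp_min(self, lo: float):
        out = Tensor(np.maximum(self.data, lo), self.requires_grad, (self,))

        def bw(g, a=self, lo=lo):
            if a.requires_grad:
                a._accumulate(g * (a.data > lo))

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum `g` down to `shape` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _binary(a, b, fwd, grads):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def bw(g, a=a, b=b):
        ga, gb = grads(g, a, b)
        if a.requires_grad:
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = bw
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution and pooling primitives
# ---------------------------------------------------------------------------

def _raw_conv(x: np.ndarray, w: np.ndarray, padding: int, dilation: int):
    """Stride-1 2-D cross-correlation of (B,C,H,W) with (O,C,k,k)."""
    O, _, k, _ = w.shape
    ke = dilation * (k - 1) + 1
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(x, (ke, ke), axis=(2, 3))[..., ::dilation, ::dilation]
    y = np.tensordot(w, win, axes=([1, 2, 3], [1, 4, 5]))  # (O,B,Ho,Wo)
    return y.transpose(1, 0, 2, 3), x


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution without window extraction."""
    y = np.tensordot(w.data[:, :, 0, 0], x.data, axes=([1], [1]))
    y = np.ascontiguousarray(y.swapaxes(0, 1))
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, any(t.requires_grad for t in parents), parents)

    def bw(g, x=x, w=w, b=b):
        if w.requires_grad:
            gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw[:, :, None, None], fresh=True)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)), fresh=True)
        if x.requires_grad:
            gx = np.tensordot(w.data[:, :, 0, 0], g, axes=([0], [1]))
            x._accumulate(np.ascontiguousarray(gx.swapaxes(0, 1)), fresh=True)

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """Differentiable stride-1 2-D cross-correlation with symmetric padding."""
    x, w = as_tensor(x), as_tensor(w)
    if x.data.shape[1] != w.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, "
            f"kernel expects {w.data.shape[1]}")
    if w.data.shape[2] == w.data.shape[3] == 1 and padding == 0:
        return _conv1x1(x, w, b)
    y, xpad = _raw_conv(x.data, w.data, padding, dilation)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, any(t.requires_grad for t in parents), parents)

    def bw(g, x=x, w=w, b=b, xpad=xpad, padding=padding, dilation=dilation):
        O, C, k, _ = w.data.shape
        if w.requires_grad:
            ke = dilation * (k - 1) + 1
            win = sliding_window_view(xpad, (ke, ke), axis=(2, 3))[
                ..., ::dilation, ::dilation]
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw, fresh=True)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)), fresh=True)
        if x.requires_grad:
            wf = w.data[:, :, ::-1, ::-1].swapaxes(0, 1)
            pad_b = dilation * (k - 1) - padding
            gx, _ = _raw_conv(np.ascontiguousarray(g), wf, pad_b, dilation)
            x._accumulate(gx, fresh=True)

    out._backward = bw
    return out


def batchnorm2d_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch norm; returns (out, batch_mean, batch_var)."""
    xd = x.data
    axes = (0, 2, 3)
    n = xd.shape[0] * xd.shape[2] * xd.shape[3]
    mu = xd.mean(axis=axes, keepdims=True)
    xc = xd - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
    out = Tensor(y, x.requires_grad or gamma.requires_grad or
                 beta.requires_grad, (x, gamma, beta))

    def bw(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, n=n):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)), fresh=True)
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)), fresh=True)
        if x.requires_grad:
            gh = g * gamma.data.reshape(1, -1, 1, 1)
            s1 = gh.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gh * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (inv / n) * (n * gh - s1 - xhat * s2)
            x._accumulate(gx.astype(x.data.dtype, copy=False), fresh=True)

    out._backward = bw
    return out, mu.ravel(), var.ravel()


def batchnorm2d_eval(x: Tensor, gamma: Tensor, beta: Tensor,
                     mean: np.ndarray, var: np.ndarray, eps: float) -> Tensor:
    """Batch norm with frozen statistics (a per-channel affine map)."""
    scale = (gamma.data / np.sqrt(var + eps)).reshape(1, -1, 1, 1).astype(
        x.data.dtype, copy=False)
    shift = (beta.data - mean * gamma.data / np.sqrt(var + eps)).reshape(
        1, -1, 1, 1).astype(x.data.dtype, copy=False)
    y = x.data * scale + shift
    out = Tensor(y, x.requires_grad or gamma.requires_grad or
                 beta.requires_grad, (x, gamma, beta))
    inv = 1.0 / np.sqrt(var + eps)

    def bw(g, x=x, gamma=gamma, beta=beta, mean=mean, inv=inv, scale=scale):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)), fresh=True)
        if gamma.requires_grad:
            xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)), fresh=True)
        if x.requires_grad:
            x._accumulate(g * scale, fresh=True)

    out._backward = bw
    return out


def maxpool2d(x: Tensor, kernel_size: int, stride: int | None = None,
              padding: int = 0) -> Tensor:
    """Max pooling; padded border uses -inf so it never wins.

    Two fast paths cover everything the networks use: 2x2/stride-2
    downsampling (disjoint windows, first-wins ties) and odd-k stride-1
    'same' pooling via a separable max filter with a shifted-mask backward
    (gradient is a valid subgradient; exact ties would share it).
    """
    x = as_tensor(x)
    k = kernel_size
    stride = stride or k
    if stride == k == 2 and padding == 0:
        return _maxpool_2x2(x)
    if stride == 1 and k % 2 == 1 and padding == k // 2:
        return _maxpool_same(x, k)
    return _maxpool_generic(x, k, stride, padding)


def _maxpool_2x2(x: Tensor) -> Tensor:
    xd = x.data
    a = xd[:, :, 0::2, 0::2]
    b = xd[:, :, 0::2, 1::2]
    c = xd[:, :, 1::2, 0::2]
    d = xd[:, :, 1::2, 1::2]
    y = np.maximum(np.maximum(a, b), np.maximum(c, d))
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g, x=x, y=y):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        taken = np.zeros(y.shape, dtype=bool)
        for u, v in ((0, 0), (0, 1), (1, 0), (1, 1)):
            sl = gx[:, :, u::2, v::2]
            win = (x.data[:, :, u::2, v::2] == y) & ~taken
            sl += g * win
            taken |= win
        x._accumulate(gx)

    out._backward = bw
    return out


def _maxpool_same(x: Tensor, k: int) -> Tensor:
    from scipy.ndimage import maximum_filter
    y = maximum_filter(x.data, size=(1, 1, k, k), mode="constant",
                       cval=-np.inf)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g, x=x, y=y, k=k):
        if not x.requires_grad:
            return
        h = k // 2
        B, C, H, W = x.data.shape
        pad = ((0, 0), (0, 0), (h, h), (h, h))
        yp = np.pad(y, pad, constant_values=np.inf)
        gp = np.pad(g, pad)
        gx = np.zeros_like(x.data)
        for du in range(k):
            for dv in range(k):
                ys = yp[:, :, du:du + H, dv:dv + W]
                gs = gp[:, :, du:du + H, dv:dv + W]
                gx += (x.data == ys) * gs
        x._accumulate(gx)

    out._backward = bw
    return out


def _maxpool_generic(x: Tensor, k: int, stride: int, padding: int) -> Tensor:
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    B, C, Hp, Wp = xd.shape
    win = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g, x=x, arg=arg, shape=(B, C, Hp, Wp), k=k, stride=stride,
           padding=padding, Ho=Ho, Wo=Wo):
        if not x.requires_grad:
            return
        B, C, Hp, Wp = shape
        oy, ox = np.divmod(arg, k)
        iy = np.arange(Ho)[None, None, :, None] * stride + oy
        ix = np.arange(Wo)[None, None, None, :] * stride + ox
        bi = np.arange(B)[:, None, None, None]
        ci = np.arange(C)[None, :, None, None]
        idx = ((bi * C + ci) * Hp + iy) * Wp + ix
        acc = np.bincount(idx.ravel(), weights=g.ravel(),
                          minlength=B * C * Hp * Wp).reshape(B, C, Hp, Wp)
        if padding:
            acc = acc[:, :, padding:-padding, padding:-padding]
        x._accumulate(acc.astype(x.data.dtype))

    out._backward = bw
    return out


def zero_stuff2d(x: Tensor, stride: int, output_padding: int = 0) -> Tensor:
    """Insert stride-1 zeros between pixels (transposed-convolution upsampling)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    Ho = (H - 1) * stride + 1 + output_padding
    Wo = (W - 1) * stride + 1 + output_padding
    y = np.zeros((B, C, Ho, Wo), dtype=x.data.dtype)
    y[:, :, ::stride, ::stride][:, :, :H, :W] = x.data
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g, x=x, stride=stride, H=H, W=W):
        if x.requires_grad:
            x._accumulate(g[:, :, ::stride, ::stride][:, :, :H, :W])

    out._backward = bw
    return out


def flip_swap_io(w: Tensor) -> Tensor:
    """Spatially flip a (Cin,Cout,k,k) kernel and swap its channel axes."""
    w = as_tensor(w)
    out = Tensor(np.ascontiguousarray(w.data[:, :, ::-1, ::-1].swapaxes(0, 1)),
                 w.requires_grad, (w,))

    def bw(g, w=w):
        if w.requires_grad:
            w._accumulate(g.swapaxes(0, 1)[:, :, ::-1, ::-1])

    out._backward = bw
    return out
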