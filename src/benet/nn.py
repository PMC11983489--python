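"""Layers, parameter containers and SGD for the numpy autodiff core."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, flip_swap_io, maxpool2d, zero_stuff2d

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Tiny nn.Module analogue: named parameters, train/eval flag, buffers."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, np.ndarray):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_buffers(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, b in self.named_buffers():
            b[...] = state["buf:" + name]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


def _kaiming(rng, shape, fan_in):
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


# module-level RNG used for default weight init; reseed via seed_init()
_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the weight-initialisation RNG (call before building a model)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    """Stride-1 2-D convolution (cross-correlation) with 'same' padding option."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, dilation: int = 1, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel_size ** 2
        self.weight = Parameter(_kaiming(
            _INIT_RNG, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        _profile_conv(self, x)
        return conv2d(x, self.weight, self.bias,
                      padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    """3x3/2x2 stride-2 transposed convolution (zero-stuff + stride-1 conv)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 2, padding: int | None = None,
                 output_padding: int = 1, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = (kernel_size - 1) // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.pad = padding
        self.output_padding = output_padding
        fan_in = in_channels * kernel_size ** 2
        self.weight = Parameter(_kaiming(
            _INIT_RNG, (in_channels, out_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        _profile_convT(self, x)
        stuffed = zero_stuff2d(x, self.stride, self.output_padding)
        w = flip_swap_io(self.weight)
        return conv2d(stuffed, w, self.bias,
                      padding=self.kernel_size - 1 - self.pad)


class BatchNorm2d(Module):
    # momentum 0.3: running statistics must track batch statistics within the
    # few hundred optimizer steps a phantom training run takes
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.3):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x):
        from .autograd import batchnorm2d_eval, batchnorm2d_train
        if self.training:
            out, mu, var = batchnorm2d_train(x, self.weight, self.bias, self.eps)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (
                mu.astype(DTYPE) - self.running_mean)
            self.running_var += self.momentum * (
                unbiased.astype(DTYPE) - self.running_var)
            return out
        return batchnorm2d_eval(x, self.weight, self.bias,
                                self.running_mean.astype(np.float64),
                                self.running_var.astype(np.float64), self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None,
                 padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x):
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (self.lr * v).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"velocity": [v.copy() for v in self.velocity]}

    def load_state_dict(self, state):
        for v, s in zip(self.velocity, state["velocity"]):
            v[...] = s


# ---------------------------------------------------------------------------
# MAC profiling (used by the complexity report)
# ---------------------------------------------------------------------------

_MAC_COUNTER: list[int] | None = None


class count_macs:
    """Context manager accumulating multiply-accumulate counts of conv layers."""

    def __enter__(self):
        global _MAC_COUNTER
        _MAC_COUNTER = [0]
        self._box = _MAC_COUNTER
        return self

    def __exit__(self, *exc):
        global _MAC_COUNTER
        _MAC_COUNTER = None

    @property
    def macs(self) -> int:
        return self._box[0]


def _profile_conv(layer: Conv2d, x):
    if _MAC_COUNTER is None:
        return
    H, W = x.data.shape[2], x.data.shape[3]
    ke = layer.dilation * (layer.kernel_size - 1) + 1
    Ho = H + 2 * layer.padding - ke + 1
    Wo = W + 2 * layer.padding - ke + 1
    _MAC_COUNTER[0] += (layer.out_channels * layer.in_channels
                        * layer.kernel_size ** 2 * Ho * Wo)


def _profile_convT(layer: ConvTranspose2d, x):
    if _MAC_COUNTER is None:
        return
    H, W = x.data.shape[2], x.data.shape[3]
    Ho = (H - 1) * layer.stride - 2 * layer.pad + layer.kernel_size \
        + layer.output_padding
    Wo = (W - 1) * layer.stride - 2 * layer.pad + layer.kernel_size \
        + layer.output_padding
    _MAC_COUNTER[0] += (layer.out_channels * layer.in_channels
                        * layer.kernel_size ** 2 * Ho * Wo)
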