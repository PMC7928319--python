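"""Layer abstractions over the autograd core.

Modules own :class:`Parameter` tensors, compose hierarchically, and expose
``state_dict``/``load_state_dict`` for checkpointing.  Convolution weights are
initialized He-normal (fan-in) from a module-level generator; call
:func:`manual_seed` before construction for bit-reproducible networks.
"""

from __future__ import annotations

import numpy as np

from . import autograd as F
from .autograd import Tensor

_rng = np.random.default_rng(0)

DTYPE = np.float32


def manual_seed(seed: int) -> None:
    """Reset the generator used for all parameter initialization."""
    global _rng
    _rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: tracks child modules and parameters by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m._named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]}")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype).reshape(p.data.shape).copy()
        for k, b in buffers.items():
            b[...] = np.asarray(state[k]).reshape(b.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._items)), m)
        self._items.append(m)
        return self

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class Identity(Module):
    def forward(self, x):
        return x


def same_padding(kernel: int, dilation: int = 1) -> tuple[int, int, int, int]:
    """Zero padding preserving spatial size at stride 1.

    Even kernels get the extra pad on top/left so output size equals input.
    """
    span = dilation * (kernel - 1)
    lead, trail = (span + 1) // 2, span // 2
    return (lead, trail, lead, trail)


class Conv2d(Module):
    """Stride-1 2-D convolution with 'same' or explicit padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, bias: bool = True, padding="same"):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.dilation = kernel, dilation
        self.pad = same_padding(kernel, dilation) if padding == "same" else tuple(padding)
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(_rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, pad=self.pad, dilation=self.dilation)


class ConvTranspose2d(Module):
    """Stride-``s`` transposed convolution (zero-insertion + correlation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 2, stride: int = 2,
                 bias: bool = True):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        std = np.sqrt(2.0 / (in_channels * kernel * kernel))
        self.weight = Parameter(_rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        z = F.zero_insert2d(x, self.stride)
        p = self.kernel - 1
        return F.conv2d(z, self.weight, self.bias, pad=(p, p, p, p))


class BilinearUpsample2d(Module):
    """Fixed (non-trainable) 2x bilinear upsampling."""

    _k1d = np.array([0.25, 0.75, 0.75, 0.25])

    def __init__(self):
        super().__init__()
        kern = np.outer(self._k1d, self._k1d).astype(DTYPE)
        self._w = Tensor(kern[None, None])

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        flat = _reshape(x, (b * c, 1, h, w))
        z = F.zero_insert2d(flat, 2)
        out = F.conv2d(z, self._w, pad=(2, 2, 2, 2))
        return _reshape(out, (b, c, 2 * h, 2 * w))


def _reshape(x: Tensor, shape) -> Tensor:
    old = x.shape

    def backward(g):
        x.accumulate(g.reshape(old))

    out = Tensor(x.data.reshape(shape))
    if x.requires_grad or x._parents:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x):
        return F.max_pool2d(x, self.size)
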