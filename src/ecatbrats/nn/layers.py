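"""Neural-network layers built on the autograd engine.

Modules mirror the familiar layer vocabulary (linear, 3D convolution,
layer/batch normalisation) with explicit, seeded initialisation: every
constructor takes a :class:`numpy.random.Generator` so that two models built
from the same seed are bitwise identical.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "Module", "ModuleList", "Linear", "Conv3d", "ConvTranspose3dX2",
    "LayerNorm", "BatchNorm3d", "upsample2x_trilinear",
]

_DTYPE = np.float32


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations (resampled)."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(_DTYPE)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # attribute scan ----------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # mode --------------------------------------------------------------------
    def train(self) -> "Module":
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # serialisation -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                bname = name[len("buffer:"):]
                owner, attr = self._resolve(bname)
                setattr(owner, attr, np.array(value))
            else:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.array(value)

    def _resolve(self, dotted: str) -> tuple["Module", str]:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        setattr(self, str(len(self._items)), module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 std: float = 0.02):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features), std))
        self.bias = Parameter(np.zeros(out_features, dtype=_DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    """Stride-1 3D convolution; padding defaults to (k-1)//2 (shape-preserving)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 bias: bool = True):
        super().__init__()
        k = int(kernel_size)
        self.padding = (k - 1) // 2 if padding is None else int(padding)
        fan_in = in_channels * k ** 3
        std = np.sqrt(2.0 / fan_in)  # He initialisation for leaky-relu stacks
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, k, k, k)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_channels, dtype=_DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias, padding=self.padding)


class ConvTranspose3dX2(Module):
    """Kernel-2 stride-2 transposed convolution: exact 2x upsampling per axis."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_channels * 8
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (in_channels, out_channels, 2, 2, 2)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_channels, dtype=_DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose3d_x2(self.weight, self.bias)


class LayerNorm(Module):
    """Normalisation over the trailing (channel) axis of token tensors."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim, dtype=_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=_DTYPE))
        self.eps = float(eps)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.weight + self.bias


class BatchNorm3d(Module):
    """Per-channel batch normalisation over (N, D, H, W)."""

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features, dtype=_DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=_DTYPE))
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3] * x.data.shape[4]
            with np.errstate(invalid="ignore"):
                unbiased = var.data * (n / max(n - 1, 1))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * unbiased.reshape(-1)
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1, 1).astype(x.dtype)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1, 1).astype(x.dtype)
            xhat = (x - mu) / sd
        shape = (1, -1, 1, 1, 1)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


def _axis_weights(n: int):
    j = np.arange(2 * n)
    pos = (j + 0.5) / 2.0 - 0.5
    i0 = np.floor(pos).astype(int)
    frac = (pos - i0).astype(_DTYPE)
    i1 = np.clip(i0 + 1, 0, n - 1)
    i0 = np.clip(i0, 0, n - 1)
    return i0, i1, (1.0 - frac), frac


def upsample2x_trilinear(x: Tensor) -> Tensor:
    """Factor-2 trilinear upsampling of the last three axes (edge-clamped).

    A fixed linear map, differentiated by applying its adjoint axis by axis.
    """
    plans = []
    data = x.data
    for ax in (-3, -2, -1):
        n = data.shape[ax]
        i0, i1, w0, w1 = _axis_weights(n)
        shape = [1] * data.ndim
        shape[ax] = 2 * n
        w0 = w0.reshape(shape)
        w1 = w1.reshape(shape)
        data = w0 * np.take(data, i0, axis=ax) + w1 * np.take(data, i1, axis=ax)
        plans.append((ax, n, i0, i1, w0, w1))

    def back(g):
        for ax, n, i0, i1, w0, w1 in reversed(plans):
            shape = list(g.shape)
            shape[ax] = n
            gsrc = np.zeros(shape, dtype=g.dtype)
            gm = np.moveaxis(gsrc, ax, 0)
            gg0 = np.moveaxis(w0 * g, ax, 0)
            gg1 = np.moveaxis(w1 * g, ax, 0)
            np.add.at(gm, i0, gg0)
            np.add.at(gm, i1, gg1)
            g = gsrc
        return (g,)

    return Tensor._make(data, (x,), back)
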