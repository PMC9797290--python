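"""Layer/module abstractions over the autodiff primitives.

Weights default to the Gaussian(0, 0.01) initialisation used throughout the
package; biases start at zero. Modules are seed-explicit: construction takes
an ``rng`` so identical seeds give identical parameters.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from . import ops
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "Conv3d",
    "ConvTranspose2d",
    "MaxPool2d",
    "MaxPool3d",
    "Linear",
    "ReLU",
    "Dropout",
    "Flatten",
]

INIT_STD = 0.01  # Gaussian init, mean 0


def _init_weight(rng: np.random.Generator, shape: tuple[int, ...], init: str) -> np.ndarray:
    """"gaussian": fixed std 0.01 (the full-scale recipe); "he": sqrt(2/fan_in)."""
    if init == "gaussian":
        std = INIT_STD
    elif init == "he":
        fan_in = int(np.prod(shape[1:])) if len(shape) > 2 else shape[0]
        std = float(np.sqrt(2.0 / fan_in))
    else:
        raise ValueError(f"unknown init {init!r}")
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    """Minimal module: tracks sub-modules and parameters, train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> Iterable["Module"]:
        yield self
        for value in self.__dict__.values():
            for m in _collect_modules(value):
                yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"expected {len(params)} arrays, got {len(state)}")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data = arr.astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Parameter]:
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        return [p for v in value for p in _collect(v)]
    if isinstance(value, dict):
        return [p for v in value.values() for p in _collect(v)]
    return []


def _collect_modules(value) -> list["Module"]:
    if isinstance(value, Module):
        return [value]
    if isinstance(value, (list, tuple)):
        return [m for v in value for m in _collect_modules(v)]
    if isinstance(value, dict):
        return [m for v in value.values() for m in _collect_modules(v)]
    return []


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        bias: bool = True,
        init: str = "gaussian",
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        pad = kernel // 2 if pad is None else pad
        self.stride, self.pad = stride, pad
        self.weight = Parameter(_init_weight(rng, (out_ch, in_ch, kernel, kernel), init))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv_nd(x, self.weight, self.bias, (self.stride,) * 2, (self.pad,) * 2)


class Conv3d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        bias: bool = True,
        init: str = "gaussian",
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        pad = kernel // 2 if pad is None else pad
        self.stride, self.pad = stride, pad
        self.weight = Parameter(
            _init_weight(rng, (out_ch, in_ch, kernel, kernel, kernel), init)
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv_nd(x, self.weight, self.bias, (self.stride,) * 3, (self.pad,) * 3)


class ConvTranspose2d(Module):
    """Learnable two-fold upsampling (kernel 2, stride 2)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        rng: np.random.Generator | None = None,
        init: str = "gaussian",
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        # fan_in for the transposed layout (C, F, 2, 2) is C * 2 * 2
        w = _init_weight(rng, (out_ch, in_ch, 2, 2), init).transpose(1, 0, 2, 3).copy()
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv_transpose2x(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, kernel: int) -> None:
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return ops.maxpool_nd(x, self.kernel)


class MaxPool3d(MaxPool2d):
    pass  # maxpool_nd is rank-generic


class Linear(Module):
    def __init__(
        self,
        in_f: int,
        out_f: int,
        rng: np.random.Generator | None = None,
        init: str = "gaussian",
    ) -> None:
        super().__init__()
        w = _init_weight(rng or np.random.default_rng(0), (out_f, in_f), init).T.copy()
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ops.add(ops.matmul(x, self.weight), self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ops.relu(x)


class Dropout(Module):
    def __init__(self, p: float = 0.5, seed: int = 0) -> None:
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return ops.dropout(x, self.p, self.rng, self.training)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ops.flatten(x)
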