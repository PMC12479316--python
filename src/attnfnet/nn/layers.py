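"""Parameterized layers built on the autodiff :class:`~attnfnet.nn.tensor.Tensor`.

Weight initialization is truncated normal (sd 0.02, resampled beyond 2 sd)
everywhere, drawn from an explicit ``numpy.random.Generator`` so that a fixed
seed reproduces a model bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d

__all__ = ["Parameter", "Module", "Linear", "Conv2d", "ConvTranspose2d", "LayerNorm"]

INIT_SD = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, sd: float = INIT_SD) -> np.ndarray:
    """Normal(0, sd) with values beyond 2 sd resampled."""
    x = rng.normal(0.0, sd, size=shape)
    bad = np.abs(x) > 2.0 * sd
    while bad.any():
        x[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(x) > 2.0 * sd
    return x


class Module:
    """Tiny container base class: tracks Parameters recursively."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float64)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch {a.shape} vs {p.data.shape}")
            p.data = a.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.w = Parameter(np.zeros((d_in, d_out)) if zero_init
                           else trunc_normal(rng, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int | tuple[int, int],
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.w = Parameter(trunc_normal(rng, (c_out, c_in, kh, kw)))
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        self.w = Parameter(trunc_normal(rng, (c_in, c_out, kernel, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b, stride=self.stride,
                                padding=self.padding)


class LayerNorm(Module):
    """Normalization over the last axis with learned affine parameters."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Parameter(np.ones(d))
        self.b = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.g + self.b
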