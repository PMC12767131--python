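"""Neural-network building blocks on top of the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "Linear", "GroupNorm", "Sequential", "SiLU"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state (de)serialization."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            params.extend(_collect(v))
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            out.update(_collect_named(v, key))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing {missing}, unexpected {extra}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}"
                )
            p.data = state[k].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v) -> list[Parameter]:
    if isinstance(v, Parameter):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, key: str) -> dict[str, Parameter]:
    if isinstance(v, Parameter):
        return {key: v}
    if isinstance(v, Module):
        return v.named_parameters(prefix=key + ".")
    if isinstance(v, (list, tuple)):
        out = {}
        for i, item in enumerate(v):
            out.update(_collect_named(item, f"{key}.{i}"))
        return out
    return {}


class Conv2d(Module):
    """3x3/1x1 convolution (stride 1) with He-normal init."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, padding: int | None = None,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Parameter(scale * rng.standard_normal((c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        scale = 0.0 if zero_init else np.sqrt(1.0 / d_in)
        self.weight = Parameter(scale * rng.standard_normal((d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GroupNorm(Module):
    """Group normalization over (C/groups, H, W) with learned scale/shift."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(B, g, (C // g) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = (xg - mu) * ((var + self.eps) ** -0.5)
        xn = xn.reshape(B, C, H, W)
        gamma = self.gamma.reshape(1, C, 1, 1)
        beta = self.beta.reshape(1, C, 1, 1)
        return xn * gamma + beta


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
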