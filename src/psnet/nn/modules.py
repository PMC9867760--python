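"""Layer abstractions over the autodiff core.

:class:`Module` tracks parameters, non-trainable buffers (batch-norm running
statistics) and submodules by attribute assignment, and supports the usual
``train()/eval()``, ``state_dict()/load_state_dict()`` and parameter
iteration contract.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module", "ModuleList", "Sequential", "Identity",
    "Conv2d", "Linear", "BatchNorm2d", "LayerNorm",
    "PReLU", "SiLU", "ReLU6", "MaxPool2d", "Upsample",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules(prefix):
            for p_name, p in mod._parameters.items():
                yield (f"{mod_name}.{p_name}" if mod_name else p_name), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for mod_name, mod in self.named_modules():
            for p_name, p in mod._parameters.items():
                state[f"{mod_name}.{p_name}" if mod_name else p_name] = p.data.copy()
            for b_name, b in mod._buffers.items():
                state[f"{mod_name}.{b_name}" if mod_name else b_name] = np.copy(b)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        own: dict[str, tuple[Module, str, bool]] = {}
        for mod_name, mod in self.named_modules():
            for p_name in mod._parameters:
                own[f"{mod_name}.{p_name}" if mod_name else p_name] = (mod, p_name, True)
            for b_name in mod._buffers:
                own[f"{mod_name}.{b_name}" if mod_name else b_name] = (mod, b_name, False)
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if strict and (missing or unexpected):
            raise KeyError(f"state dict mismatch: missing={sorted(missing)[:5]}, "
                           f"unexpected={sorted(unexpected)[:5]}")
        for key, value in state.items():
            if key not in own:
                continue
            mod, attr, is_param = own[key]
            if is_param:
                param = mod._parameters[attr]
                if param.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{param.data.shape} vs {value.shape}")
                param.data = value.astype(param.data.dtype).copy()
            else:
                mod._set_buffer(attr, np.copy(value))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._list = []
        for i, m in enumerate(modules):
            self._modules[str(i)] = m
            self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming_fan_in(shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    bound = math.sqrt(1.0 / max(fan_in, 1))
    return np.random.default_rng(abs(hash(shape)) % (2 ** 31)).uniform(
        -bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size, *,
                 stride: int = 1, padding=0, dilation: int = 1,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel_size if isinstance(kernel_size, (tuple, list))
                  else (kernel_size, kernel_size))
        if groups not in (1, in_channels):
            raise ValueError("only dense (groups=1) or depthwise convolutions supported")
        if groups == in_channels and out_channels != in_channels:
            raise ValueError("depthwise convolution must preserve channel count")
        wshape = (out_channels, in_channels // groups, kh, kw)
        self.weight = Parameter(_kaiming_fan_in(wshape))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming_fan_in((out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None
        self.in_features, self.out_features = in_features, out_features

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import matmul
        out = matmul(x, self.weight.transpose(1, 0))
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics in training, running in eval."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))
        self.eps, self.momentum, self.num_features = eps, momentum, num_features

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, m, v = F.batch_norm_train(x, self.weight, self.bias, self.eps)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = v * (n / max(n - 1, 1))
            mom = self.momentum
            self._set_buffer("running_mean",
                             (1 - mom) * self.running_mean + mom * m)
            self._set_buffer("running_var",
                             (1 - mom) * self.running_var + mom * unbiased)
            return out
        # inference: fold running stats into one affine transform
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.weight * Tensor(invstd)).reshape(1, -1, 1, 1)
        shift = (self.bias - self.weight * Tensor(self.running_mean * invstd)
                 ).reshape(1, -1, 1, 1)
        return x * scale + shift


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class PReLU(Module):
    """Rectifier with a single learnable negative-side slope."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.slope = Parameter(np.array([init], dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.prelu(x, self.slope)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.silu(x)


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        from .tensor import relu6
        return relu6(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel)


class Upsample(Module):
    """Bilinear upsampling by an integer scale factor."""

    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return F.resize_bilinear(x, (h * self.scale, w * self.scale))
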