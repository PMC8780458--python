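"""Composable network modules over the autodiff kit.

The API follows the conventions common to deep-learning frameworks:
modules own :class:`Parameter` leaves and submodules, expose
``parameters()`` / ``state_dict()``, and carry a training-mode flag that
batch normalization consults.  Construction is deterministic given the
``rng`` handed to each layer (Glorot-uniform weights, zero biases).
"""

from __future__ import annotations

from typing import Callable, Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor, as_tensor


class Parameter(Tensor):
    """A trainable tensor leaf."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base class: parameter/submodule registry, mode flags, hooks."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_forward_hooks", [])
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

    # -- traversal ----------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mname, mod in self.named_modules():
            for pname, p in mod._parameters.items():
                yield (f"{mname}.{pname}" if mname else pname), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for mname, mod in self.named_modules():
            for bname, b in mod._buffers.items():
                yield (f"{mname}.{bname}" if mname else bname), b

    # -- modes --------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = True
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({k: b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            if k not in state:
                raise KeyError(f"missing parameter in checkpoint: {k}")
            if state[k].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {state[k].shape}, "
                    f"model {p.data.shape}")
            p.data[...] = state[k]
        for k, b in self.named_buffers():
            if k in state:
                b[...] = state[k]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    # -- hooks / call --------------------------------------------------------
    def register_forward_hook(self, fn: Callable) -> Callable[[], None]:
        """``fn(module, output)`` runs after every forward; returns a remover."""
        self._forward_hooks.append(fn)

        def remove():
            self._forward_hooks.remove(fn)

        return remove

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        for hook in self._forward_hooks:
            hook(self, out)
        return out

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


def count_parameters(module: Module) -> int:
    """Number of trainable scalars (normalization running statistics are
    buffers and therefore excluded)."""
    return int(sum(p.size for p in module.parameters()))


def format_millions(n: int, decimals: int = 1) -> str:
    """Render a parameter count in millions at the given rounding precision,
    half-up (e.g. ``28,360,058 -> '28.4 M'``)."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-decimals) if decimals else Decimal(1)
    v = (Decimal(n) / Decimal(10 ** 6)).quantize(q, rounding=ROUND_HALF_UP)
    return f"{v} M"


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return F.relu6(x)


class Flatten(Module):
    def forward(self, x):
        return F.flatten(x)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(glorot_uniform(
            rng, (in_features, out_features), in_features, out_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = F._pair(kernel_size)
        if padding == "same":
            padding = F.same_padding((kh, kw))
        self.stride, self.padding = stride, padding
        fan_in, fan_out = in_channels * kh * kw, out_channels * kh * kw
        self.weight = Parameter(glorot_uniform(
            rng, (out_channels, in_channels, kh, kw), fan_in, fan_out))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size, stride=1, padding=0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = F._pair(kernel_size)
        if padding == "same":
            padding = F.same_padding((kh, kw))
        self.stride, self.padding = stride, padding
        self.weight = Parameter(glorot_uniform(
            rng, (channels, kh, kw), kh * kw, kh * kw))
        self.bias = Parameter(np.zeros(channels, np.float32)) if bias else None

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias,
                                  self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalization with trainable per-channel scale and shift.
    Works on (N, C, H, W) and (N, C) inputs alike."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))

    def forward(self, x):
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return F.avg_pool2d(x, self.kernel_size, self.stride, self.padding)


class GlobalAvgPool(Module):
    def forward(self, x):
        return F.global_avg_pool(x)
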