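"""Neural-network layers, containers and the Adam optimiser.

Thin, torch-like module system over :mod:`nodulecascade.autodiff`.
Parameters are ``Tensor`` objects with ``requires_grad=True``; buffers
(batch-norm running statistics) are plain numpy arrays.  Weight
initialisation is explicit: builders call ``Module.init_weights(rng)``
with a seeded generator, so identical seeds give bit-identical models.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, avg_pool2d, bilinear_resize, concat, conv2d

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "SeparableConv2d", "BatchNorm2d", "ReLU", "Sigmoid",
    "Linear", "GlobalAvgPool2d", "Adam",
    "avg_pool2d", "bilinear_resize", "concat",
]


def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    w = rng.normal(0.0, std, size=shape)
    return np.clip(w, -2.0 * std, 2.0 * std).astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._mods.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for mname, m in self._mods.items():
            yield from m.named_buffers(prefix + mname + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- state ----------------------------------------------------------------

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs: dict[str, tuple[Module, str]] = {}

        # buffers are replaced, not written in place, so track owners
        def _buffer_owners(mod: Module, prefix: str = ""):
            for name in mod._buffers:
                bufs[prefix + name] = (mod, name)
            for mname, sub in mod._mods.items():
                _buffer_owners(sub, prefix + mname + ".")
        _buffer_owners(self)
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(f"state mismatch; missing={sorted(missing)[:3]} "
                             f"extra={sorted(extra)[:3]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, (mod, bname) in bufs.items():
            mod._buffers[bname] = state[name].copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def init_weights(self, rng: np.random.Generator) -> None:
        for m in self.modules():
            m.reset_parameters(rng)

    def reset_parameters(self, rng: np.random.Generator) -> None:  # overridable
        pass

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._seq = list(mods)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel_size: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channels must be divisible by groups")
        self.cin, self.cout = cin, cout
        self.kernel_size, self.stride = kernel_size, stride
        self.padding, self.dilation, self.groups = padding, dilation, groups
        k = kernel_size
        self.weight = Tensor(np.zeros((cout, cin // groups, k, k), np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def reset_parameters(self, rng):
        fan_in = self.cin // self.groups * self.kernel_size ** 2
        self.weight.data = _trunc_normal(rng, self.weight.shape, np.sqrt(2.0 / fan_in))
        if self.bias is not None:
            self.bias.data = np.zeros(self.cout, np.float32)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation,
                      groups=self.groups)


class SeparableConv2d(Module):
    """Depthwise 3x3 (or kxk) convolution followed by a 1x1 pointwise one.

    The stride lives on the depthwise stage, so a stride-2 separable
    convolution is the down-sampling primitive used everywhere in place of
    max pooling.
    """

    def __init__(self, cin: int, cout: int, kernel_size: int = 3, *,
                 stride: int = 1, dilation: int = 1, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = dilation * (kernel_size // 2)
        self.depthwise = Conv2d(cin, cin, kernel_size, stride=stride,
                                padding=padding, dilation=dilation,
                                groups=cin, bias=False)
        self.pointwise = Conv2d(cin, cout, 1, bias=False)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(channels, np.float32)
        self._buffers["running_var"] = np.ones(channels, np.float32)

    def reset_parameters(self, rng):
        self.gamma.data = np.ones(self.channels, np.float32)
        self.beta.data = np.zeros(self.channels, np.float32)
        self._buffers["running_mean"][:] = 0.0
        self._buffers["running_var"][:] = 1.0

    def forward(self, x):
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1.0 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1.0 - m
            self._buffers["running_var"] += m * var.data.reshape(-1)
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            mu = self._buffers["running_mean"].reshape(1, -1, 1, 1)
            var = self._buffers["running_var"].reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))
        return xhat * g + b


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.weight = Tensor(np.zeros((cin, cout), np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def reset_parameters(self, rng):
        self.weight.data = _trunc_normal(rng, self.weight.shape,
                                         np.sqrt(2.0 / self.cin))
        if self.bias is not None:
            self.bias.data = np.zeros(self.cout, np.float32)

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GlobalAvgPool2d(Module):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x):
        return x.mean(axis=(2, 3))


class Adam:
    """Adam with optional decoupled weight decay (applied directly to the
    weights, not through the moment estimates)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
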