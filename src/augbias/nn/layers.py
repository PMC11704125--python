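"""Neural-network layers and a minimal SGD optimizer on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "ReLU",
    "GlobalAvgPool",
    "Sequential",
    "MLP",
    "SGD",
    "ema_update",
    "copy_params",
]


class Module:
    """Base class: children discovered by attribute inspection."""

    def children(self) -> list["Module"]:
        out: list[Module] = []
        for v in vars(self).values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(item for item in v if isinstance(item, Module))
        return out

    def walk(self) -> list["Module"]:
        mods = [self]
        for c in self.children():
            mods.extend(c.walk())
        return mods

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool):
        for m in self.walk():
            if hasattr(m, "training"):
                m.training = flag

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=p.data.dtype)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = Tensor(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_dim)
        self.w = Tensor(rng.normal(0.0, scale, (in_dim, out_dim)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W); running stats at eval."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, ch, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1), dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros((1, ch, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, ch, 1, 1), dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ad.batchnorm2d(x, self.gamma, self.beta, eps=self.eps)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            return out
        xh = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xh * self.gamma + self.beta


class GlobalAvgPool(Module):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class MLP(Sequential):
    """Linear-ReLU stack; last layer linear."""

    def __init__(self, dims: list[int], rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        mods: list[Module] = []
        for i in range(len(dims) - 1):
            mods.append(Linear(dims[i], dims[i + 1], rng=rng))
            if i < len(dims) - 2:
                mods.append(ReLU())
        super().__init__(*mods)


class SGD:
    """Momentum SGD with optional weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _norm_pairs(src: Module, dst: Module):
    return [(a, b) for a, b in zip(src.walk(), dst.walk())
            if isinstance(a, BatchNorm2d) and isinstance(b, BatchNorm2d)]


def copy_params(src: Module, dst: Module):
    dst.load_state_arrays([a.copy() for a in src.state_arrays()])
    for a, b in _norm_pairs(src, dst):
        b.running_mean = a.running_mean.copy()
        b.running_var = a.running_var.copy()


def ema_update(online: Module, target: Module, momentum: float):
    """target <- momentum * target + (1 - momentum) * online, in place.

    Normalization running statistics are copied from the online network."""
    for po, pt in zip(online.parameters(), target.parameters()):
        pt.data = momentum * pt.data + (1.0 - momentum) * po.data
    for a, b in _norm_pairs(online, target):
        b.running_mean = a.running_mean.copy()
        b.running_var = a.running_var.copy()
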