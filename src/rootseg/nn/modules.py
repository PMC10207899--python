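"""Layer containers built on the autograd core.

A deliberately small `Module` system: parameter registration by attribute
assignment, recursive `state_dict`/`load_state_dict` over flat name paths,
and train/eval mode propagation (BatchNorm is the only mode-sensitive
layer).
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state ---------------------------------------------------------
    def state_dict(self, prefix: str = "") -> "OrderedDict[str, np.ndarray]":
        out: OrderedDict[str, np.ndarray] = OrderedDict()
        for k, p in self._params.items():
            out[prefix + k] = p.data
        for k, b in self._buffers.items():
            out[prefix + k] = b
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state: dict) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(
                f"state dict mismatch: missing={sorted(missing)[:5]} "
                f"unexpected={sorted(unexpected)[:5]}")
        for name, arr in state.items():
            obj: Module = self
            parts = name.split(".")
            for part in parts[:-1]:
                obj = obj._modules[part]
            leaf = parts[-1]
            if leaf in obj._params:
                if obj._params[leaf].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                obj._params[leaf].data = np.asarray(arr, dtype=np.float32)
            else:
                obj._set_buffer(leaf, np.asarray(arr))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan: int) -> np.ndarray:
    """He-normal init with the given fan (fan_out for convs here)."""
    std = np.sqrt(2.0 / fan)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_out = c_out * kernel * kernel
        self.weight = Parameter(
            kaiming_normal(rng, (c_out, c_in, kernel, kernel), fan_out))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    """Affine map over the trailing axis."""

    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(kaiming_normal(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32))

    def forward(self, x):
        return ag.matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel.

    Training mode normalizes with batch statistics and updates running
    estimates; eval mode uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        c = self.gamma.data.shape[0]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._set_buffer(
                "running_mean",
                (1 - m) * self.running_mean + m * mu.data.reshape(c))
            self._set_buffer(
                "running_var",
                (1 - m) * self.running_var + m * var.data.reshape(c))
            inv = ag.power(var + self.eps, -0.5)
            xhat = xc * inv
        else:
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape)
            xhat = (x - self.running_mean.reshape(shape)) * inv
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class SGDM:
    """SGD with classical momentum and L2 weight decay.

    Update: v <- momentum*v + grad + wd*p ; p <- p - lr*v
    (the convention of the common deep-learning SGDM implementations).
    """

    def __init__(self, params: list[Parameter], momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def save_state(path, module: Module) -> None:
    """Serialize a module's weights and buffers to an .npz archive."""
    np.savez(path, **module.state_dict())


def load_state(path, module: Module) -> None:
    with np.load(path) as f:
        module.load_state_dict({k: f[k] for k in f.files})
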