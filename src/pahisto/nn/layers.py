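"""Layers and the Module/parameter system used by all networks."""

from __future__ import annotations

import json

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "ModuleList", "Conv2d", "Linear", "InstanceNorm2d",
    "BatchNorm2d", "Sequential", "ReLU", "LeakyReLU", "Tanh",
    "save_state", "load_state",
]


class Module:
    """Base class; parameters and buffers are discovered by attribute
    traversal.  Buffers (non-trainable state such as batch-norm running
    statistics) are plain numpy arrays named in ``_buffer_names``."""

    _buffer_names: tuple = ()
    train_mode: bool = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield f"{prefix}{name}", getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{cname}.")

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def set_training(self, flag: bool):
        for m in self.modules():
            m.train_mode = flag
        return self

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        for k, v in self.named_buffers():
            out["~" + k] = np.asarray(v).copy()
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        own_buf = {"~" + k for k, _ in self.named_buffers()}
        missing = (set(own) | own_buf) - set(state)
        extra = set(state) - set(own) - own_buf
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for k, _ in self.named_buffers():
            parts = k.split(".")
            obj = self
            for part in parts[:-1]:
                obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
            setattr(obj, parts[-1], np.asarray(state["~" + k]).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        self.stride = stride
        self.padding = padding
        self.weight = Tensor(_kaiming(rng, (out_ch, in_ch, k, k), in_ch * k * k),
                             requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, np.float32), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_f, out_f), np.float32)
        else:
            w = _kaiming(rng, (in_f, out_f), in_f)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with affine parameters.

    Used as the single normalization flavour across all networks: it has no
    running statistics, so train/eval behaviour is identical and results do
    not depend on batch composition.
    """

    def __init__(self, ch: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, ch, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1), np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training mode normalizes with batch statistics and updates exponential
    running estimates; eval mode (``set_training(False)``) uses the stored
    running statistics, making inference independent of batch composition.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, ch, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1), np.float32), requires_grad=True)
        self.running_mean = np.zeros(ch, np.float32)
        self.running_var = np.ones(ch, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.train_mode:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
            xn = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xn * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Sequential(Module):
    def __init__(self, *modules):
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


def save_state(path, module: Module, meta: dict | None = None,
               version: int = 1):
    """Serialize parameters plus a JSON metadata header to an .npz file."""
    state = module.state_dict()
    header = json.dumps({"format_version": version, "meta": meta or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **state)


def load_state(path, module: Module) -> dict:
    """Load parameters saved by :func:`save_state`; returns the metadata."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        state = {k: z[k] for k in z.files if k != "__header__"}
    module.load_state_dict(state)
    return header
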