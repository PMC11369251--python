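"""Minimal reverse-mode automatic differentiation on numpy arrays.

All trainable models in this package (the virtual-staining generator and
discriminator, the U-Net, the classification backbones) are built from the
`Tensor` operations defined here.  The engine is deliberately small: float32
arrays, a dynamic tape, and only the operations the networks need.  Every
operation is deterministic, so fixed seeds reproduce training histories
bitwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bwd(g):
            base = self.data
            if exponent == 2.0:
                local = 2.0 * base
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    local = exponent * base ** (exponent - 1.0)
                local = np.nan_to_num(local, nan=0.0, posinf=0.0, neginf=0.0)
            self._accum(g * local)

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), bwd)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), bwd)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities --------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bwd(g):
            self._accum(g * np.where(mask, 1.0, slope).astype(np.float32))

        return Tensor._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ez = np.exp(self.data[~pos])
        out_data[~pos] = ez / (1.0 + ez)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def softplus(self):
        # log(1 + e^x), numerically stable; derivative is sigmoid(x)
        out_data = np.logaddexp(0.0, self.data).astype(np.float32)

        def bwd(g):
            sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
            self._accum(g * sig.astype(np.float32))

        return Tensor._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)
        out_data = np.abs(self.data)

        def bwd(g):
            self._accum(g * sign)

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    # -- spatial ops (NCHW) ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation via im2col.  x: (N,C,H,W), w: (F,C,kh,kw)."""
        x = self.data
        w = weight.data
        N, C, H, W = x.shape
        F, Cw, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        Hp, Wp = xp.shape[2], xp.shape[3]
        oh = (Hp - kh) // stride + 1
        ow = (Wp - kw) // stride + 1
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp,
            shape=(N, C, kh, kw, oh, ow),
            strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        ).reshape(N, C * kh * kw, oh * ow)
        wmat = w.reshape(F, C * kh * kw)
        out = np.matmul(wmat, cols)          # (F,K) @ (N,K,L) -> (N,F,L)
        out = out.reshape(N, F, oh, ow)
        if bias is not None:
            out = out + bias.data.reshape(1, F, 1, 1)

        def bwd(g):
            gmat = g.reshape(N, F, oh * ow)
            if weight.requires_grad:
                gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
                weight._accum(gw.reshape(F, C, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = np.matmul(wmat.T, gmat)
                dcols = dcols.reshape(N, C, kh, kw, oh, ow)
                dxp = np.zeros((N, C, Hp, Wp), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + oh * stride : stride,
                            j : j + ow * stride : stride] += dcols[:, :, i, j]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accum(dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, bwd)

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of an NCHW tensor."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        N, C, H, W = self.data.shape

        def bwd(g):
            self._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

        return Tensor._make(out_data, (self,), bwd)

    def avg_pool2d(self, k: int = 2):
        N, C, H, W = self.data.shape
        if H % k or W % k:
            raise ValueError("avg_pool2d requires dims divisible by k")
        out_data = self.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

        def bwd(g):
            gexp = g.repeat(k, axis=2).repeat(k, axis=3) / (k * k)
            self._accum(gexp.astype(np.float32))

        return Tensor._make(out_data, (self,), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), bwd)
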