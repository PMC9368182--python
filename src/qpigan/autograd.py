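"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the tensor operations the generator, discriminator and
training loop need: broadcast arithmetic, (batched) matmul, shape ops,
strided/transposed convolution, pooling-style reductions and the usual
activations.  Gradients are accumulated by topological-order backward
passes.  Everything is float32 by default and deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- graph construction helper -----------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            return [(self, _unbroadcast(g, self.shape)), (other, _unbroadcast(g, other.shape))]
        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            return [(self, -g)]
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            return [
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ]
        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            return [
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data ** 2, other.shape)),
            ]
        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        def bw(g):
            return [(self, g * exponent * self.data ** (exponent - 1))]
        return Tensor._make(self.data ** exponent, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return [(self, _unbroadcast(ga, self.shape)), (other, _unbroadcast(gb, other.shape))]
        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- elementwise functions ---------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        def bw(g):
            return [(self, g * out_data)]
        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            return [(self, g / self.data)]
        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def bw(g):
            return [(self, g * 0.5 / out_data)]
        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bw(g):
            return [(self, g * (1.0 - out_data ** 2))]
        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)
        def bw(g):
            return [(self, g * sign)]
        return Tensor._make(np.abs(self.data), (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope).astype(np.float32)
        def bw(g):
            return [(self, g * mask)]
        return Tensor._make(self.data * mask, (self,), bw)

    def relu(self):
        return self.leaky_relu(0.0)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)
        def bw(g):
            dt = (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * x ** 2)
            return [(self, g * (0.5 * (1.0 + t) + 0.5 * x * dt))]
        return Tensor._make(out_data.astype(np.float32), (self,), bw)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.shape).copy())]
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g2, self.shape).copy())]
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        def bw(g):
            return [(self, g.reshape(old))]
        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def bw(g):
            return [(self, g.transpose(inv))]
        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros(self.shape, dtype=np.float32)
            np.add.at(full, idx, g)
            return [(self, full)]
        return Tensor._make(self.data[idx], (self,), bw)

    def roll(self, shift: tuple[int, ...], axis: tuple[int, ...]):
        def bw(g):
            return [(self, np.roll(g, tuple(-s for s in shift), axis))]
        return Tensor._make(np.roll(self.data, shift, axis), (self,), bw)

    def pad2d(self, pad: int):
        """Zero-pad the trailing two axes by ``pad`` on each side."""
        if pad == 0:
            return self
        widths = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        def bw(g):
            sl = tuple([slice(None)] * (self.ndim - 2) + [slice(pad, -pad), slice(pad, -pad)])
            return [(self, g[sl])]
        return Tensor._make(np.pad(self.data, widths), (self,), bw)

    def upsample_nearest(self, factor: int):
        """Nearest-neighbour upsampling of an (..., H, W) tensor."""
        f = int(factor)
        out_data = self.data.repeat(f, axis=-2).repeat(f, axis=-1)
        h, w = self.shape[-2], self.shape[-1]
        def bw(g):
            g = g.reshape(g.shape[:-2] + (h, f, w, f))
            return [(self, g.sum(axis=(-3, -1)))]
        return Tensor._make(out_data, (self,), bw)

    # -- convolution ----------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution (cross-correlation); x (B,C,H,W), w (O,C,k,k)."""
        x = self.pad2d(padding)
        xd, wd = x.data, weight.data
        b_, c, h, w_ = xd.shape
        o, c2, kh, kw = wd.shape
        if c != c2:
            raise ValueError("channel mismatch in conv2d")
        ho = (h - kh) // stride + 1
        wo = (w_ - kw) // stride + 1
        out_data = np.zeros((b_, o, ho, wo), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                patch = xd[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                out_data += np.einsum("bchw,oc->bohw", patch, wd[:, :, i, j])

        def bw(g):
            gx = np.zeros_like(xd)
            gw = np.zeros_like(wd)
            for i in range(kh):
                for j in range(kw):
                    patch = xd[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                    gw[:, :, i, j] = np.einsum("bohw,bchw->oc", g, patch)
                    gx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += (
                        np.einsum("bohw,oc->bchw", g, wd[:, :, i, j]))
            return [(x, gx), (weight, gw)]

        out = Tensor._make(out_data, (x, weight), bw)
        if bias is not None:
            out = out + bias.reshape(1, -1, 1, 1)
        return out

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0) -> "Tensor":
        """Transposed convolution; x (B,C,H,W), w (C,O,k,k).

        Output spatial size is (H−1)·stride − 2·padding + k.
        """
        xd, wd = self.data, weight.data
        b_, c, h, w_ = xd.shape
        c2, o, kh, kw = wd.shape
        if c != c2:
            raise ValueError("channel mismatch in conv_transpose2d")
        hp = (h - 1) * stride + kh
        wp = (w_ - 1) * stride + kw
        yp = np.zeros((b_, o, hp, wp), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                yp[:, :, i:i + stride * h:stride, j:j + stride * w_:stride] += (
                    np.einsum("bchw,co->bohw", xd, wd[:, :, i, j]))
        ho, wo = hp - 2 * padding, wp - 2 * padding
        out_data = yp[:, :, padding:padding + ho, padding:padding + wo]

        def bw(g):
            gp = np.zeros((b_, o, hp, wp), dtype=np.float32)
            gp[:, :, padding:padding + ho, padding:padding + wo] = g
            gx = np.zeros_like(xd)
            gw = np.zeros_like(wd)
            for i in range(kh):
                for j in range(kw):
                    gsub = gp[:, :, i:i + stride * h:stride, j:j + stride * w_:stride]
                    gx += np.einsum("bohw,co->bchw", gsub, wd[:, :, i, j])
                    gw[:, :, i, j] = np.einsum("bchw,bohw->co", xd, gsub)
            return [(self, gx), (weight, gw)]

        out = Tensor._make(out_data.copy(), (self, weight), bw)
        if bias is not None:
            out = out + bias.reshape(1, -1, 1, 1)
        return out

    # -- composites ------------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(np.max(self.data, axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


class Parameter(Tensor):
    """A leaf tensor tracked by optimizers."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even inside no_grad


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        outs = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            outs.append((t, g[tuple(sl)]))
        return outs

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


class Adam:
    """Adam optimizer with optional linear learning-rate decay."""

    def __init__(self, params: Iterable[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
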