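"""Neural-network building blocks on the numpy autodiff core.

Contains the generic layers (linear, convolutions, normalisations, MLP) and
the windowed multi-head self-attention machinery: scaled dot-product
attention, window partition/reverse, cyclic shifting with cross-border
masking, relative position bias and patch merging.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "LayerNorm",
    "InstanceNorm2d",
    "Mlp",
    "scaled_dot_attention",
    "window_partition",
    "window_reverse",
    "cyclic_shift",
    "shift_attention_mask",
    "WindowAttention",
    "SwinBlock",
    "PatchMerging",
]


class Module:
    """Tiny module base: collects Parameters recursively, saves/loads state."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in vars(self).values():
            out.extend(_collect(value))
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            _collect_state(value, f"{prefix}{name}", state)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        own = self.state_dict(prefix)
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)[:5]} ...")
        # rebuild the same traversal and copy in place
        for name, value in vars(self).items():
            _load_state(value, f"{prefix}{name}", state)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Parameter]:
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Parameter] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_state(value, key: str, state: dict[str, np.ndarray]) -> None:
    if isinstance(value, Parameter):
        state[key] = value.data
    elif isinstance(value, Module):
        state.update(value.state_dict(prefix=key + "."))
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _collect_state(v, f"{key}.{i}", state)


def _load_state(value, key: str, state: dict[str, np.ndarray]) -> None:
    if isinstance(value, Parameter):
        value.data = np.asarray(state[key], dtype=np.float32).reshape(value.data.shape)
    elif isinstance(value, Module):
        value.load_state_dict({k[len(key) + 1:]: v for k, v in state.items()
                               if k.startswith(key + ".")})
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _load_state(v, f"{key}.{i}", state)


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, std: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, std: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, std, (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride,
                                  padding=self.padding)


class LayerNorm(Module):
    """Normalisation over the trailing feature axis, with affine scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over (H, W); no affine terms."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(-2, -1), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(-2, -1), keepdims=True)
        return centered / (var + self.eps).sqrt()


class Mlp(Module):
    """Two-layer GELU MLP used inside attention blocks."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


# --------------------------------------------------------------------------
# attention primitives
# --------------------------------------------------------------------------

def scaled_dot_attention(q, k, v, mask=None):
    """softmax(QKᵀ/√d_k)·V with rows of the weight matrix summing to 1.

    Accepts arrays of shape (..., n, d); a numpy input yields a numpy
    output, a Tensor input stays on the autodiff graph.  ``mask`` (additive,
    broadcastable to the (..., n, n) logits) disables forbidden pairs.
    """
    as_numpy = not isinstance(q, Tensor)
    qt = q if isinstance(q, Tensor) else Tensor(q)
    kt = k if isinstance(k, Tensor) else Tensor(k)
    vt = v if isinstance(v, Tensor) else Tensor(v)
    for name, t in (("q", qt), ("k", kt), ("v", vt)):
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"non-finite values in {name}")
    if qt.shape[-1] != kt.shape[-1]:
        raise ValueError("q and k must share the key dimension d_k")
    if kt.shape[-2] != vt.shape[-2]:
        raise ValueError("k and v must share the row count")
    d_k = qt.shape[-1]
    logits = (qt @ kt.transpose(*range(kt.ndim - 2), kt.ndim - 1, kt.ndim - 2)) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        logits = logits + (mask if isinstance(mask, Tensor) else Tensor(mask))
    weights = logits.softmax(axis=-1)
    out = weights @ vt
    return out.numpy() if as_numpy else out


def window_partition(feature, window: int):
    """(B, H, W, C) → (B·nW, window², C) non-overlapping row-major windows.

    Also accepts an unbatched (H, W, C) input, returning (nW, window², C).
    """
    x = feature if isinstance(feature, Tensor) else np.asarray(feature)
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    b, h, w, c = x.shape
    if h % window or w % window:
        raise ValueError(f"grid {h}x{w} not divisible by window {window}")
    x = x.reshape(b, h // window, window, w // window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // window) * (w // window), window * window, c)


def window_reverse(windows, window: int, h: int, w: int):
    """Inverse of :func:`window_partition`; returns (B, H, W, C) (or (H, W, C))."""
    as_numpy = not isinstance(windows, Tensor)
    x = windows if isinstance(windows, Tensor) else np.asarray(windows)
    n, _, c = x.shape
    nw = (h // window) * (w // window)
    b = n // nw
    x = x.reshape(b, h // window, w // window, window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    out = x.reshape(b, h, w, c)
    if as_numpy and b == 1 and n == nw:
        out = out.reshape(h, w, c)
    return out


def cyclic_shift(feature, shift: int, inverse: bool = False):
    """Circular roll of an (..., H, W, C) feature by (−shift, −shift).

    ``inverse=True`` rolls back by (+shift, +shift).  A pure permutation:
    no values are created or lost; cross-border attention after a shift is
    suppressed separately via :func:`shift_attention_mask`.
    """
    s = shift if inverse else -shift
    if not isinstance(feature, Tensor):
        arr = np.asarray(feature)
        return np.roll(arr, (s, s), (arr.ndim - 3, arr.ndim - 2))
    return feature.roll((s, s), (feature.ndim - 3, feature.ndim - 2))


def shift_attention_mask(h: int, w: int, window: int, shift: int) -> np.ndarray:
    """Additive attention mask (nW, window², window²) for shifted windows.

    Tokens wrapped across the true image border receive −100 logits toward
    tokens from a different region, reproducing the nine-region scheme of
    shifted-window attention.
    """
    if shift == 0:
        nw = (h // window) * (w // window)
        return np.zeros((nw, window * window, window * window), dtype=np.float32)
    region = np.zeros((h, w), dtype=np.int64)
    idx = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            region[hs, ws] = idx
            idx += 1
    region = window_partition(region[:, :, None].astype(np.float64), window)[..., 0]
    diff = region[:, :, None] - region[:, None, :]
    return np.where(diff == 0, 0.0, -100.0).astype(np.float32)


def _relative_position_index(window: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel + (window - 1)
    return (rel[0] * (2 * window - 1) + rel[1]).astype(np.int64)


class WindowAttention(Module):
    """Multi-head self-attention inside a window, with learned relative
    position bias (one scalar per head and per relative offset)."""

    def __init__(self, dim: int, num_heads: int, window: int, rng: np.random.Generator):
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.dim = dim
        self.num_heads = num_heads
        self.window = window
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias = Parameter(rng.normal(0.0, 0.02, ((2 * window - 1) ** 2, num_heads)))
        self._rel_index = _relative_position_index(window).reshape(-1)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw, n, c = x.shape
        heads, dh = self.num_heads, c // self.num_heads
        qkv = self.qkv(x).reshape(bw, n, 3, heads, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (bw, heads, n, dh)
        bias = self.rel_bias[self._rel_index].reshape(n, n, heads).transpose(2, 0, 1)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)) + bias
        if mask is not None:
            nw = mask.shape[0]
            logits = logits.reshape(bw // nw, nw, heads, n, n) + Tensor(mask[None, :, None])
            logits = logits.reshape(bw, heads, n, n)
        out = logits.softmax(axis=-1) @ v
        out = out.transpose(0, 2, 1, 3).reshape(bw, n, c)
        return self.proj(out)


class SwinBlock(Module):
    """One (shifted-)window transformer block: LN → (S)W-MSA → LN → MLP,
    each with a residual connection."""

    def __init__(self, dim: int, num_heads: int, window: int, shift: int,
                 rng: np.random.Generator, mlp_ratio: float = 4.0):
        if not 0 <= shift < window:
            raise ValueError("need 0 <= shift < window")
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self.window = window
        self.shift = shift
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        shortcut = x
        y = self.norm1(x)
        if self.shift:
            y = cyclic_shift(y, self.shift)
            key = (h, w)
            if key not in self._mask_cache:
                self._mask_cache[key] = shift_attention_mask(h, w, self.window, self.shift)
            mask = self._mask_cache[key]
        else:
            mask = None
        y = window_partition(y, self.window)
        y = self.attn(y, mask=mask)
        y = window_reverse(y, self.window, h, w)
        if self.shift:
            y = cyclic_shift(y, self.shift, inverse=True)
        x = shortcut + y
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    """Swin downsampling: concatenate 2×2 patch neighbourhoods (4C) and
    project linearly to 2C, halving both spatial dimensions."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"patch merging needs even dims, got {h}x{w}")
        tl = x[:, 0::2, 0::2, :]
        bl = x[:, 1::2, 0::2, :]
        tr = x[:, 0::2, 1::2, :]
        br = x[:, 1::2, 1::2, :]
        merged = concat([tl, bl, tr, br], axis=-1)
        return self.reduction(merged)
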