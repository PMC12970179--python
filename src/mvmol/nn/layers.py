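"""Neural building blocks on the autodiff tensor: linear/embedding layers,
layer norm, multi-head self-attention, transformer blocks and 2D convolution
(im2col).  Parameter initialization is seeded through each module's ``rng``
argument so identical seeds give identical parameters.
"""

from __future__ import annotations

import numpy as np

from mvmol.nn.tensor import Tensor, concatenate, softmax

NEG_INF = -1e9


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(np.float64)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _param(rng: np.random.Generator, *shape: int, scale: float | None = None) -> Tensor:
    """Xavier/Glorot-style uniform initialization."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[-1]
        scale = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = _param(rng, in_dim, out_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out if self.bias is None else out + self.bias


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n_embeddings, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.int64)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard softmax self-attention; optionally records attention probs."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.record_attention = False
        self.last_attention: np.ndarray | None = None  # (B, H, T, T)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, T, D = x.shape
        qkv = self.qkv(x).reshape(B, T, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        if pad_mask is not None:
            # pad_mask: (B, T) with 1 = real token; keys at pads get -inf
            add = np.where(pad_mask[:, None, None, :] > 0, 0.0, NEG_INF)
            scores = scores + Tensor(add)
        probs = softmax(scores, axis=-1)
        if self.record_attention:
            self.last_attention = probs.data.copy()
        out = probs @ v  # (B, H, T, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer block: attention + 2-layer feed-forward."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 2):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim, rng)
        self.ff2 = Linear(ff_mult * dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), pad_mask)
        return x + self.ff2(self.ff1(self.norm2(x)).relu())


def masked_mean_pool(x: Tensor, pad_mask: np.ndarray | None) -> Tensor:
    """Mean over the token axis, excluding padded positions."""
    if pad_mask is None:
        return x.mean(axis=1)
    m = np.asarray(pad_mask, dtype=np.float64)[:, :, None]
    denom = np.maximum(m.sum(axis=1), 1.0)
    return (x * Tensor(m)).sum(axis=1) / Tensor(denom)


class Conv2d(Module):
    """Channels-last 2D convolution via strided patch views (valid padding).

    Weights are stored flat with patch layout (C, kh, kw) so the forward is
    one tensordot over the sliding-window view, with no materialized im2col
    copy.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        self.kernel, self.stride = kernel, stride
        self.in_channels, self.out_channels = in_channels, out_channels
        self.weight = _param(rng, kernel * kernel * in_channels, out_channels)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        w, bias = self.weight, self.bias
        cin, cout = self.in_channels, self.out_channels
        win = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (B, ho, wo, C, k, k), a view
        w4 = w.data.reshape(cin, k, k, cout)
        out_data = np.tensordot(win, w4, axes=([3, 4, 5], [0, 1, 2])) + bias.data

        def backward(g):
            dw = np.tensordot(win, g, axes=([0, 1, 2], [0, 1, 2]))  # (C, k, k, cout)
            db = g.sum(axis=(0, 1, 2))
            dpatch = np.tensordot(g, w4, axes=([3], [3]))  # (B, ho, wo, C, k, k)
            dx = np.zeros(x.shape)
            ho, wo = g.shape[1], g.shape[2]
            for a in range(k):
                for b in range(k):
                    dx[:, a : a + s * ho : s, b : b + s * wo : s, :] += dpatch[
                        :, :, :, :, a, b
                    ]
            return ((x, dx), (w, dw.reshape(w.shape)), (bias, db))

        return Tensor(out_data, _parents=(x, w, bias), _backward=backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling, channels-last."""
    B, H, W, C = x.shape
    ho, wo = H // k, W // k
    out_data = x.data[:, : ho * k, : wo * k, :].reshape(B, ho, k, wo, k, C).mean(axis=(2, 4))

    def backward(g):
        dx = np.zeros(x.shape)
        dx[:, : ho * k, : wo * k, :] = np.repeat(
            np.repeat(g, k, axis=1), k, axis=2
        ) / (k * k)
        return ((x, dx),)

    return Tensor(out_data, _parents=(x,), _backward=backward)
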