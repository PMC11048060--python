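"""Transformer building blocks and an AdamW optimizer on top of ``_tensor``.

Layers follow the pre-LayerNorm convention (LN -> sublayer -> residual),
which keeps small models stable without warmup.  Parameters are plain
:class:`~rrg._tensor.Tensor` leaves registered in a flat ``{name: Tensor}``
dict so checkpointing is a single ``np.savez``.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, gelu, softmax


class ParamStore:
    """Flat named parameter registry shared by all layers of one model."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: dict[str, Tensor] = {}

    def add(self, name: str, shape: tuple, scale: float = 0.02) -> Tensor:
        if name in self.params:
            raise ValueError(f"duplicate parameter name: {name}")
        if scale == 0.0:
            data = np.zeros(shape)
        else:
            data = self.rng.normal(0.0, scale, size=shape)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(state)
        extra = set(state) - set(self.params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={missing} extra={extra}")
        for k, v in self.params.items():
            if v.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = np.array(state[k], dtype=np.float64)


class Linear:
    def __init__(self, store: ParamStore, name: str, d_in: int, d_out: int):
        self.w = store.add(f"{name}.w", (d_in, d_out))
        self.b = store.add(f"{name}.b", (d_out,), scale=0.0)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm:
    def __init__(self, store: ParamStore, name: str, dim: int, eps: float = 1e-5):
        self.g = store.add(f"{name}.g", (dim,), scale=0.0)
        self.b = store.add(f"{name}.b", (dim,), scale=0.0)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * (self.g + 1.0) + self.b


class MultiHeadAttention:
    """Self- or cross-attention.  ``mask`` is additive (0 / -inf-like)."""

    def __init__(self, store: ParamStore, name: str, dim: int, n_heads: int):
        if dim % n_heads:
            raise ValueError("model dim must be divisible by n_heads")
        self.h = n_heads
        self.dh = dim // n_heads
        self.q = Linear(store, f"{name}.q", dim, dim)
        self.k = Linear(store, f"{name}.k", dim, dim)
        self.v = Linear(store, f"{name}.v", dim, dim)
        self.o = Linear(store, f"{name}.o", dim, dim)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.h, self.dh).swapaxes(1, 2)

    def __call__(self, x: Tensor, kv: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, T, _ = x.shape
        Bkv, S, _ = kv.shape  # batch-1 memory broadcasts over beams
        q = self._split(self.q(x), B, T)          # (B, H, T, dh)
        k = self._split(self.k(kv), Bkv, S)
        v = self._split(self.v(kv), Bkv, S)
        scores = (q @ k.swapaxes(-1, -2)) * (self.dh ** -0.5)  # (B, H, T, S)
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = softmax(scores, axis=-1)
        out = (attn @ v).swapaxes(1, 2).reshape(B, T, self.h * self.dh)
        return self.o(out)


class FeedForward:
    def __init__(self, store: ParamStore, name: str, dim: int, hidden: int):
        self.fc1 = Linear(store, f"{name}.fc1", dim, hidden)
        self.fc2 = Linear(store, f"{name}.fc2", hidden, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class EncoderLayer:
    def __init__(self, store: ParamStore, name: str, dim: int, n_heads: int, hidden: int):
        self.ln1 = LayerNorm(store, f"{name}.ln1", dim)
        self.attn = MultiHeadAttention(store, f"{name}.attn", dim, n_heads)
        self.ln2 = LayerNorm(store, f"{name}.ln2", dim)
        self.ff = FeedForward(store, f"{name}.ff", dim, hidden)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h)
        x = x + self.ff(self.ln2(x))
        return x


class DecoderLayer:
    """Causal self-attention + cross-attention to visual features + FFN."""

    def __init__(self, store: ParamStore, name: str, dim: int, n_heads: int, hidden: int):
        self.ln1 = LayerNorm(store, f"{name}.ln1", dim)
        self.self_attn = MultiHeadAttention(store, f"{name}.self", dim, n_heads)
        self.ln2 = LayerNorm(store, f"{name}.ln2", dim)
        self.cross_attn = MultiHeadAttention(store, f"{name}.cross", dim, n_heads)
        self.ln3 = LayerNorm(store, f"{name}.ln3", dim)
        self.ff = FeedForward(store, f"{name}.ff", dim, hidden)

    def __call__(self, x: Tensor, memory: Tensor,
                 self_mask: np.ndarray | None,
                 cross_mask: np.ndarray | None) -> Tensor:
        h = self.ln1(x)
        x = x + self.self_attn(h, h, self_mask)
        x = x + self.cross_attn(self.ln2(x), memory, cross_mask)
        x = x + self.ff(self.ln3(x))
        return x


def causal_mask(T: int) -> np.ndarray:
    """Additive (1, 1, T, T) mask: position t attends to <= t only."""
    m = np.zeros((1, 1, T, T))
    m[..., np.triu_indices(T, k=1)[0], np.triu_indices(T, k=1)[1]] = -1e30
    return m


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients in place so the global L2 norm is <= max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            if self.wd and not k.endswith((".b", ".g")):
                p.data -= self.lr * self.wd * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
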