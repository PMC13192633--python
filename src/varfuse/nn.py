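"""Transformer building blocks, optimizer, and LR schedule on the autodiff core.

Everything here follows the conventions of small pre-LN transformers: each
sublayer is ``x + f(LN(x))``, attention is scaled dot-product with additive
masks, and initialisation is scaled-normal from a caller-supplied
``numpy.random.Generator`` so whole models are reproducible from one seed.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from ._tensor import Tensor, concat, gelu, layer_norm, softmax

NEG_INF = -1e9  # additive mask value


def parameter(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / math.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = state[name].astype(p.data.dtype).copy()

    def named_tensors(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        """Every Tensor attribute, trainable or frozen."""
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_tensors(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_tensors(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out.append((f"{key}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def freeze(self) -> None:
        for _, p in self.named_tensors():
            p.requires_grad = False
            p.grad = None

    @property
    def frozen(self) -> bool:
        return all(not p.requires_grad for _, p in self.named_tensors())


def _collect(value) -> Iterable[Tensor]:
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _collect(item)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True):
        self.weight = parameter(rng, (d_in, d_out))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, num: int, dim: int):
        self.weight = parameter(rng, (num, dim), scale=0.02)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, eps=self.eps)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; queries and key/value source may differ."""

    def __init__(self, rng: np.random.Generator, dim: int, num_heads: int,
                 kv_dim: int | None = None):
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        kv_dim = kv_dim if kv_dim is not None else dim
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, kv_dim, dim)
        self.wv = Linear(rng, kv_dim, dim)
        self.wo = Linear(rng, dim, dim)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, xq: Tensor, xkv: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """``mask`` is additive, broadcastable to (B, heads, Tq, Tk); 0 = keep."""
        q = self._split(self.wq(xq))
        k = self._split(self.wk(xkv))
        v = self._split(self.wv(xkv))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1, additive_mask=mask)
        out = attn @ v
        b, _, t, _ = out.shape
        out = out.transpose(0, 2, 1, 3).reshape(b, t, self.num_heads * self.head_dim)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, rng: np.random.Generator, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    """Pre-LN block: self-attention, optional cross-attention, feed-forward.

    ``self_prefix`` lets callers extend the self-attention key/value sequence
    with extra tokens (e.g. query tokens acting as a soft prompt) without those
    tokens being updated by the block.
    """

    def __init__(self, rng: np.random.Generator, dim: int, num_heads: int,
                 ff_width: int, cross: bool = False, cross_kv_dim: int | None = None):
        self.ln_self = LayerNorm(dim)
        self.self_attn = MultiHeadAttention(rng, dim, num_heads)
        self.has_cross = cross
        if cross:
            self.ln_cross = LayerNorm(dim)
            self.cross_attn = MultiHeadAttention(rng, dim, num_heads, kv_dim=cross_kv_dim)
        self.ln_ff = LayerNorm(dim)
        self.ffn = FeedForward(rng, dim, ff_width)

    def __call__(self, x: Tensor, self_mask: np.ndarray | None = None,
                 self_prefix: Tensor | None = None,
                 cross_kv: Tensor | None = None,
                 cross_mask: np.ndarray | None = None,
                 cross_update_mask: np.ndarray | None = None) -> Tensor:
        h = self.ln_self(x)
        kv = h if self_prefix is None else concat([self.ln_self(self_prefix), h], axis=1)
        x = x + self.self_attn(h, kv, mask=self_mask)
        if self.has_cross and cross_kv is not None:
            upd = self.cross_attn(self.ln_cross(x), cross_kv, mask=cross_mask)
            if cross_update_mask is not None:
                upd = upd * Tensor(cross_update_mask)
            x = x + upd
        x = x + self.ffn(self.ln_ff(x))
        return x


def causal_mask(t: int, prefix: int = 0) -> np.ndarray:
    """Additive mask where position i attends to all ``prefix`` slots and j <= i."""
    m = np.full((t, prefix + t), NEG_INF)
    m[:, :prefix] = 0.0
    tri = np.triu(np.full((t, t), NEG_INF), k=1)
    m[:, prefix:] = tri
    return m


def padding_mask(lengths: np.ndarray, t: int) -> np.ndarray:
    """Additive key mask (B, 1, 1, t) hiding positions beyond each length."""
    lengths = np.asarray(lengths)
    m = np.where(np.arange(t)[None, :] < lengths[:, None], 0.0, NEG_INF)
    return m[:, None, None, :]


class AdamW:
    """Decoupled weight-decay Adam over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_warmup_lr(step: int, total_steps: int, base_lr: float,
                     warmup_frac: float = 0.1) -> float:
    """Linear warmup from 0 over ``warmup_frac`` of steps, then cosine decay to 0."""
    if not 0.0 < warmup_frac < 1.0:
        raise ValueError("warmup fraction must lie in (0, 1)")
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return base_lr * step / warmup
    progress = (step - warmup) / max(1, total_steps - warmup)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * min(progress, 1.0)))


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients so the global L2 norm is at most ``max_norm``; returns pre-clip norm."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for g in grads:
            g *= scale
    return norm
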