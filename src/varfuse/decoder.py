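"""A tiny causal text decoder used as the frozen generation backbone.

The decoder is a conventional pre-LN causal transformer over a small
vocabulary. Once constructed through :func:`varfuse.synthetic.tiny_frozen_decoder`
its parameters are flagged non-trainable: gradients flow *through* its
activations to the multimodal prefix, but never into its weights — the same
contract a frozen large language model obeys during prefix conditioning.
"""

from __future__ import annotations

import hashlib

import numpy as np

from ._tensor import Tensor, concat, no_grad
from . import nn


class TinyCausalDecoder(nn.Module):
    def __init__(self, rng: np.random.Generator, vocab_size: int, dim: int = 48,
                 num_layers: int = 2, num_heads: int = 4, max_len: int = 256):
        if vocab_size < 8:
            raise ValueError(f"vocab_size must be at least 8, got {vocab_size}")
        self.vocab_size = vocab_size
        self.dim = dim
        self.max_len = max_len
        self.token_emb = nn.Embedding(rng, vocab_size, dim)
        self.pos_emb = nn.parameter(rng, (max_len, dim), scale=0.02)
        self.blocks = [
            nn.TransformerBlock(rng, dim, num_heads, 4 * dim) for _ in range(num_layers)
        ]
        self.ln_f = nn.LayerNorm(dim)
        self.lm_head = nn.Linear(rng, dim, vocab_size)

    @property
    def embedding_dim(self) -> int:
        """Dimension of the token-embedding space the prefix must live in."""
        return self.dim

    def __call__(self, prefix: Tensor | None, token_ids: np.ndarray) -> Tensor:
        """Logits (B, P+T, vocab) over the prefix-then-text sequence.

        ``prefix`` is (B, P, dim) soft tokens already in embedding space;
        ``token_ids`` is (B, T) integer ids. Attention is causal over the
        whole sequence, so every text position sees the full prefix.
        """
        token_ids = np.asarray(token_ids, dtype=np.intp)
        if token_ids.ndim != 2:
            raise ValueError("token_ids must be (batch, time)")
        b, t = token_ids.shape
        x = self.token_emb(token_ids) + self.pos_emb[:t]
        if prefix is not None:
            if prefix.shape[-1] != self.dim:
                raise ValueError(
                    f"prefix dim {prefix.shape[-1]} != decoder embedding dim {self.dim}"
                )
            x = concat([prefix, x], axis=1)
        total = x.shape[1]
        mask = nn.causal_mask(total)
        for blk in self.blocks:
            x = blk(x, self_mask=mask)
        return self.lm_head(self.ln_f(x))

    def greedy_decode(self, prefix: Tensor | None, prompt_ids: list[int],
                      max_new_tokens: int, eos_id: int | None = None) -> list[int]:
        """Deterministic greedy continuation of ``prompt_ids`` given a prefix."""
        ids = list(prompt_ids)
        plen = 0 if prefix is None else prefix.shape[1]
        with no_grad():
            for _ in range(max_new_tokens):
                if plen + len(ids) >= self.max_len:
                    break
                logits = self(prefix, np.asarray([ids]))
                nxt = int(np.argmax(logits.data[0, -1]))
                ids.append(nxt)
                if eos_id is not None and nxt == eos_id:
                    break
        return ids[len(prompt_ids):]

    def weight_checksum(self) -> str:
        """SHA-256 over all parameter bytes in name order (frozen-weight audits)."""
        named = sorted(self.named_tensors())
        h = hashlib.sha256()
        for name, _ in named:
            h.update(name.encode())
        for _, t in named:
            h.update(np.ascontiguousarray(t.data).tobytes())
        return h.hexdigest()
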