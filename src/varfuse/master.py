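"""Stage-2 master querying transformer: instruction-conditioned fusion.

The master model holds a fixed set of meta-query vectors. At each forward
pass the meta-queries and the tokenised instruction are concatenated into a
single sequence: meta-queries self-attend with each other and with the
instruction tokens, and cross-attend — every ``cross_attn_period``-th layer —
to the layer-normalised concatenation of all Stage-1 modality query tokens.
Only the meta-query positions are emitted; a linear projection ``W_proj``
maps them into the frozen decoder's token-embedding space, yielding the
fixed-length multimodal prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ._tensor import Tensor, concat
from . import nn

IGNORE_INDEX = -100  # label value excluded from the next-token loss

MODALITY_ORDER = ("sequence", "gene", "protein")


@dataclass
class MasterConfig:
    decoder_dim: int
    num_layers: int = 6
    num_meta_queries: int = 32
    cross_attn_period: int = 2
    hidden_dim: int = 128  # matches the Stage-1 d_q so no adapter is needed
    num_heads: int = 8
    ff_width: int | None = None
    instr_vocab_size: int = 64
    max_instr_len: int = 64

    def __post_init__(self):
        if self.ff_width is None:
            self.ff_width = 4 * self.hidden_dim
        if self.hidden_dim % self.num_heads:
            raise ValueError("hidden_dim must be divisible by num_heads")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "MasterConfig":
        return cls(**json.loads(s))


@dataclass
class MultimodalPrefix:
    """Fixed-length prefix in decoder embedding space, with provenance."""

    vectors: Tensor  # (B, num_meta_queries, decoder_dim)
    provenance: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.vectors.shape[1]


class MasterQFormer(nn.Module):
    def __init__(self, config: MasterConfig, rng: np.random.Generator):
        self.config = config
        d = config.hidden_dim
        self.meta_queries = nn.parameter(rng, (config.num_meta_queries, d), scale=0.02)
        # dedicated instruction embedding table (not the decoder's)
        self.instr_emb = nn.Embedding(rng, config.instr_vocab_size, d)
        self.instr_pos = nn.parameter(rng, (config.max_instr_len, d), scale=0.02)
        self.kv_layernorm = nn.LayerNorm(d)  # applied to Stage-1 tokens before every cross-attn
        self.blocks = [
            nn.TransformerBlock(
                rng, d, config.num_heads, config.ff_width,
                cross=(layer % config.cross_attn_period == 0), cross_kv_dim=d,
            )
            for layer in range(config.num_layers)
        ]
        self.ln_f = nn.LayerNorm(d)
        self.w_proj = nn.Linear(rng, d, config.decoder_dim, bias=False)

    def fuse(self, modality_tokens: dict[str, Tensor] | list[Tensor],
             instruction_ids: np.ndarray | None = None) -> MultimodalPrefix:
        """Fuse Stage-1 query tokens (any nonempty modality subset) and an
        instruction into exactly ``num_meta_queries`` projected prefix vectors."""
        if isinstance(modality_tokens, dict):
            provenance = [m for m in MODALITY_ORDER if m in modality_tokens]
            provenance += [m for m in modality_tokens if m not in MODALITY_ORDER]
            token_list = [modality_tokens[m] for m in provenance]
        else:
            token_list = list(modality_tokens)
            provenance = [f"modality_{i}" for i in range(len(token_list))]
        if not token_list:
            raise ValueError("at least one modality's query tokens are required")
        d = self.config.hidden_dim
        for tok in token_list:
            if tok.shape[-1] != d:
                raise ValueError(f"token dim {tok.shape[-1]} != master hidden dim {d}")
        stage1 = concat(token_list, axis=1)  # (B, sum K_i, d)
        b = stage1.shape[0]
        nm = self.config.num_meta_queries

        ones = Tensor(np.ones((b, 1, 1)))
        x = ones * self.meta_queries.reshape(1, nm, d)
        t_instr = 0
        if instruction_ids is not None:
            instruction_ids = np.asarray(instruction_ids, dtype=np.intp)
            if instruction_ids.ndim == 1:
                instruction_ids = np.broadcast_to(instruction_ids, (b, instruction_ids.shape[0]))
            t_instr = instruction_ids.shape[1]
        if t_instr > 0:
            if t_instr > self.config.max_instr_len:
                raise ValueError("instruction exceeds max_instr_len")
            instr = self.instr_emb(instruction_ids) + self.instr_pos[:t_instr]
            x = concat([x, instr], axis=1)
        # instruction positions take part in self-attention but receive no
        # cross-attention update and are not emitted
        upd_mask = np.ones((1, nm + t_instr, 1))
        upd_mask[:, nm:] = 0.0
        for blk in self.blocks:
            x = blk(
                x,
                cross_kv=self.kv_layernorm(stage1) if blk.has_cross else None,
                cross_update_mask=upd_mask if blk.has_cross else None,
            )
        meta_out = self.ln_f(x[:, :nm, :])
        return MultimodalPrefix(vectors=self.w_proj(meta_out), provenance=provenance)


def assemble_decoder_input(prefix: MultimodalPrefix, prompt_ids: list[int],
                           answer_ids: list[int] | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Build the decoder token sequence and per-position loss labels.

    Input order is prefix tokens, then prompt, then answer. The label at each
    prefix and prompt position is ``IGNORE_INDEX``; each answer position's
    label is its own token id. Returns ``(token_ids (T,), labels (P+T,))``.
    """
    if prefix is None:
        raise ValueError("prefix is required")
    answer_ids = answer_ids or []
    tokens = np.asarray(list(prompt_ids) + list(answer_ids), dtype=np.intp)
    p = prefix.length
    labels = np.full(p + len(tokens), IGNORE_INDEX, dtype=np.intp)
    labels[p + len(prompt_ids):] = answer_ids
    return tokens, labels


def masked_ntp_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Next-token cross-entropy over positions whose label is not IGNORE_INDEX.

    ``logits`` is (B, S, V); ``labels`` is (B, S) aligned with the input, so the
    label at position s is predicted from the logits at position s - 1.
    """
    from ._tensor import log_softmax  # local import avoids a cycle at module load

    labels = np.asarray(labels, dtype=np.intp)
    shifted = labels[:, 1:]
    keep = shifted != IGNORE_INDEX
    if not keep.any():
        raise ValueError("no unmasked label positions")
    rows, cols = np.nonzero(keep)
    lp = log_softmax(logits[:, :-1, :], axis=-1)
    picked = lp[rows, cols, shifted[rows, cols]]
    return -picked.mean()
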