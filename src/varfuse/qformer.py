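"""Modality-specific querying transformer and the three caption-alignment losses.

A querying transformer (Q-former) distills a variable-length modality
embedding into K learned query vectors via cross-attention. Stage-1 training
aligns each modality's query tokens with the paired variant caption through
three objectives:

* **contrastive** (ITC): symmetric InfoNCE between l2-normalized query and
  pooled-text projections with a learnable temperature; per-pair similarity
  is the maximum over the K query tokens;
* **matching** (ITM): binary classification of (query tokens, caption) pairs
  with hard negatives mined from the ITC similarity matrix;
* **grounded generation** (ITG): causal language modeling of the caption
  with the query tokens visible to every text position as a soft prompt.

The text encoder/decoder shares the Q-former's transformer blocks (one
parameter set, task-dependent masks): bidirectional for ITC/ITM text
encoding, causal for ITG.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from ._tensor import Tensor, concat, log_softmax
from . import nn

ITC_TAU_INIT = 1.0 / 14.3  # inverse-temperature init 14.3


@dataclass
class QFormerConfig:
    input_dim: int
    num_layers: int = 12
    hidden_dim: int = 128
    num_heads: int = 8
    ff_width: int | None = None  # defaults to 4 * hidden_dim
    num_queries: int = 32
    cross_attn_period: int = 2
    vocab_size: int = 64
    max_text_len: int = 96
    proj_dim: int = 64

    def __post_init__(self):
        if self.hidden_dim % self.num_heads:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} not divisible by num_heads {self.num_heads}"
            )
        if self.cross_attn_period < 1:
            raise ValueError("cross_attn_period must be at least 1")
        if self.ff_width is None:
            self.ff_width = 4 * self.hidden_dim

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "QFormerConfig":
        return cls(**json.loads(s))


class QFormer(nn.Module):
    """One modality's querying transformer plus its text side and loss heads."""

    def __init__(self, config: QFormerConfig, rng: np.random.Generator):
        self.config = config
        d = config.hidden_dim
        self.queries = nn.parameter(rng, (config.num_queries, d), scale=0.02)
        self.input_proj = nn.Linear(rng, config.input_dim, d)
        self.blocks = [
            nn.TransformerBlock(
                rng, d, config.num_heads, config.ff_width,
                cross=(layer % config.cross_attn_period == 0), cross_kv_dim=d,
            )
            for layer in range(config.num_layers)
        ]
        self.ln_f = nn.LayerNorm(d)
        self.token_emb = nn.Embedding(rng, config.vocab_size, d)
        self.pos_emb = nn.parameter(rng, (config.max_text_len, d), scale=0.02)
        self.proj_q = nn.Linear(rng, d, config.proj_dim)
        self.proj_t = nn.Linear(rng, d, config.proj_dim)
        self.log_tau = Tensor(np.array(math.log(ITC_TAU_INIT)), requires_grad=True)
        self.itm_head = nn.Linear(rng, d, 2)
        self.lm_head = nn.Linear(rng, d, config.vocab_size)

    @property
    def tau(self) -> Tensor:
        return self.log_tau.exp()

    # -- encoders ---------------------------------------------------------

    def encode(self, embeddings: Tensor | np.ndarray,
               lengths: np.ndarray | None = None) -> Tensor:
        """Distill (B, T, input_dim) modality embeddings into (B, K, d) query tokens.

        Cross-attention to the (projected) input fires at every
        ``cross_attn_period``-th layer, starting at layer 0. ``lengths`` masks
        padded input rows.
        """
        embeddings = Tensor._wrap(embeddings)
        if embeddings.ndim == 2:
            embeddings = embeddings.reshape(1, *embeddings.shape)
        if embeddings.shape[-1] != self.config.input_dim:
            raise ValueError(
                f"input dim mismatch: expected {self.config.input_dim}, "
                f"got {embeddings.shape[-1]}"
            )
        b, t, _ = embeddings.shape
        kv = self.input_proj(embeddings)
        cross_mask = None if lengths is None else nn.padding_mask(lengths, t)
        ones = Tensor(np.ones((b, 1, 1)))
        x = ones * self.queries.reshape(1, *self.queries.shape)
        for blk in self.blocks:
            x = blk(x, cross_kv=kv if blk.has_cross else None, cross_mask=cross_mask)
        return self.ln_f(x)

    def _embed_text(self, token_ids: np.ndarray) -> Tensor:
        token_ids = np.asarray(token_ids, dtype=np.intp)
        t = token_ids.shape[-1]
        if t > self.config.max_text_len:
            raise ValueError(f"text length {t} exceeds max_text_len {self.config.max_text_len}")
        return self.token_emb(token_ids) + self.pos_emb[:t]

    def encode_text(self, token_ids: np.ndarray,
                    lengths: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        """Bidirectional text encoding; returns (per-token (B,T,d), mean-pooled (B,d))."""
        token_ids = np.asarray(token_ids, dtype=np.intp)
        b, t = token_ids.shape
        x = self._embed_text(token_ids)
        mask = None if lengths is None else nn.padding_mask(lengths, t)
        for blk in self.blocks:
            x = blk(x, self_mask=mask)
        x = self.ln_f(x)
        if lengths is None:
            pooled = x.mean(axis=1)
        else:
            w = (np.arange(t)[None, :] < np.asarray(lengths)[:, None]).astype(float)
            w /= w.sum(axis=1, keepdims=True)
            pooled = (x * Tensor(w[:, :, None])).sum(axis=1)
        return x, pooled

    # -- contrastive ------------------------------------------------------

    def project_queries(self, query_tokens: Tensor) -> Tensor:
        q = self.proj_q(query_tokens)
        norm = ((q ** 2.0).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
        return q * norm

    def project_text(self, pooled_text: Tensor) -> Tensor:
        tproj = self.proj_t(pooled_text)
        norm = ((tproj ** 2.0).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
        return tproj * norm

    def similarity_matrix(self, query_tokens: Tensor, pooled_text: Tensor) -> Tensor:
        """(B, B) cosine similarities; entry (i, j) is the max over the K query
        tokens of item i against the text projection of item j."""
        qhat = self.project_queries(query_tokens)        # (B, K, p)
        that = self.project_text(pooled_text)            # (B, p)
        sims = qhat @ that.swapaxes(0, 1).reshape(1, that.shape[1], that.shape[0])
        return sims.max(axis=1)                          # (B, B)

    def itc_loss(self, query_tokens: Tensor, pooled_text: Tensor) -> Tensor:
        """Symmetric two-direction InfoNCE over the in-batch similarity matrix."""
        b = query_tokens.shape[0]
        if b < 1:
            raise ValueError("empty batch")
        sims = self.similarity_matrix(query_tokens, pooled_text)
        logits = sims * (1.0 / self.tau)
        diag = np.arange(b)
        row_lp = log_softmax(logits, axis=1)[diag, diag]
        col_lp = log_softmax(logits, axis=0)[diag, diag]
        return -0.5 * (row_lp.mean() + col_lp.mean())

    # -- matching ---------------------------------------------------------

    def itm_logits(self, query_tokens: Tensor, token_ids: np.ndarray) -> Tensor:
        """Two-way match logits: query tokens attend to the caption embeddings."""
        text = self._embed_text(np.asarray(token_ids, dtype=np.intp))
        x = query_tokens
        for blk in self.blocks:
            x = blk(x, self_prefix=text)
        return self.itm_head(self.ln_f(x).mean(axis=1))

    def itm_loss(self, pairs: list[tuple[Tensor, np.ndarray, int]]) -> Tensor:
        """Mean binary cross-entropy over labeled (query tokens, caption, match) pairs."""
        if not pairs:
            raise ValueError("itm_loss requires at least one pair")
        qtoks = concat([q if q.ndim == 3 else q.reshape(1, *q.shape) for q, _, _ in pairs], axis=0)
        max_t = max(len(ids) for _, ids, _ in pairs)
        padded = np.zeros((len(pairs), max_t), dtype=np.intp)
        for i, (_, ids, _) in enumerate(pairs):
            padded[i, : len(ids)] = ids
        labels = np.array([lab for _, _, lab in pairs], dtype=np.intp)
        logits = self.itm_logits(qtoks, padded)
        return binary_match_loss(logits, labels)

    # -- grounded generation ------------------------------------------------

    def itg_logits(self, query_tokens: Tensor, token_ids: np.ndarray) -> Tensor:
        """Causal LM logits over the caption with query tokens as a soft prompt."""
        token_ids = np.asarray(token_ids, dtype=np.intp)
        x = self._embed_text(token_ids)
        t = token_ids.shape[-1]
        k = query_tokens.shape[1]
        mask = nn.causal_mask(t, prefix=k)
        for blk in self.blocks:
            x = blk(x, self_mask=mask, self_prefix=query_tokens)
        return self.lm_head(self.ln_f(x))

    def itg_loss(self, query_tokens: Tensor, token_ids: np.ndarray,
                 lengths: np.ndarray | None = None) -> Tensor:
        """Mean per-token causal cross-entropy of the paired caption."""
        token_ids = np.asarray(token_ids, dtype=np.intp)
        if token_ids.ndim == 1:
            token_ids = token_ids[None, :]
            query_tokens = query_tokens if query_tokens.ndim == 3 else query_tokens.reshape(
                1, *query_tokens.shape)
        if token_ids.shape[1] < 2:
            raise ValueError("caption must contain at least one transition")
        logits = self.itg_logits(query_tokens, token_ids)
        return causal_lm_loss(logits, token_ids, lengths=lengths)


# -- loss primitives (shared with the Stage-2 trainer) --------------------------


def binary_match_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean two-way cross-entropy; ``labels`` in {0 (no match), 1 (match)}."""
    lp = log_softmax(logits, axis=-1)
    n = len(labels)
    return -lp[np.arange(n), np.asarray(labels, dtype=np.intp)].mean()


def causal_lm_loss(logits: Tensor, token_ids: np.ndarray,
                   lengths: np.ndarray | None = None) -> Tensor:
    """Mean next-token cross-entropy: logits at position t score token t+1.

    ``logits`` may include extra leading (prefix) positions; only the trailing
    ``T`` positions are scored. ``lengths`` limits scoring to real tokens.
    """
    token_ids = np.asarray(token_ids, dtype=np.intp)
    b, t = token_ids.shape
    text_logits = logits[:, logits.shape[1] - t:, :]
    lp = log_softmax(text_logits, axis=-1)
    rows, cols = np.meshgrid(np.arange(b), np.arange(t - 1), indexing="ij")
    targets = token_ids[:, 1:]
    tok_lp = lp[rows, cols, targets]  # (B, T-1)
    if lengths is None:
        return -tok_lp.mean()
    valid = (np.arange(1, t)[None, :] < np.asarray(lengths)[:, None]).astype(float)
    return -(tok_lp * Tensor(valid)).sum() / float(valid.sum())


def mine_hard_negatives(similarity_matrix: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample one text-negative and one embedding-negative per item.

    For item i the text negative j != i is drawn with probability proportional
    to softmax over row i of the similarity matrix (diagonal excluded); the
    embedding negative is drawn from column i likewise. Returns
    ``(text_neg_idx, emb_neg_idx)``, each shape (B,). B=1 yields empty arrays
    with a warning — there is nothing to mine.
    """
    s = np.asarray(similarity_matrix, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {s.shape}")
    b = s.shape[0]
    if b < 2:
        warnings.warn("batch of size 1: no negatives available")
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)

    def sample(weights_row: np.ndarray, exclude: int) -> int:
        w = np.exp(weights_row - weights_row.max())
        w[exclude] = 0.0
        w /= w.sum()
        return int(rng.choice(b, p=w))

    text_neg = np.array([sample(s[i, :].copy(), i) for i in range(b)], dtype=np.intp)
    emb_neg = np.array([sample(s[:, i].copy(), i) for i in range(b)], dtype=np.intp)
    return text_neg, emb_neg


def stage1_total_loss(per_modality_losses: list[tuple]) -> Tensor:
    """Plain unweighted sum of (ITC, ITM, ITG) across modalities."""
    if not per_modality_losses:
        raise ValueError("at least one modality required")
    total = None
    for triple in per_modality_losses:
        for term in triple:
            total = term if total is None else total + term
    return total if isinstance(total, Tensor) else Tensor(np.array(float(total)))


def encode_modality(model: QFormer, embedding, lengths=None) -> Tensor:
    """Functional alias for :meth:`QFormer.encode`."""
    return model.encode(embedding, lengths=lengths)
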