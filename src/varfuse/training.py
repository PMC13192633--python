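"""Two-stage optimization of the fusion architecture, plus two ablations.

Stage 1 jointly trains every modality-specific Q-former on the plain sum of
its contrastive, matching, and grounded-generation losses. Stage 2 trains
the master Q-former, the decoder projection, and (through the next-token
gradient only) the Stage-1 Q-formers, while the text decoder stays frozen.
Optimization is AdamW with decoupled weight decay, a cosine schedule with
linear warmup over 10% of steps, and gradient clipping at global norm 1.0.

The two ablations mirror the architecture probes: *permutation* deranges
embeddings against their captions (alignment must collapse to chance), and
*master removal* replaces the fusion model by per-modality projections whose
tokens are prepended directly to the decoder prompt.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._tensor import Tensor, no_grad
from . import nn
from .decoder import TinyCausalDecoder
from .evaluate import FieldReport, per_field_accuracy
from .master import (
    IGNORE_INDEX,
    MasterConfig,
    MasterQFormer,
    MODALITY_ORDER,
    MultimodalPrefix,
    assemble_decoder_input,
    masked_ntp_loss,
)
from .qformer import QFormer, QFormerConfig, mine_hard_negatives, stage1_total_loss
from .synthetic import DimSpec, VariantItem
from .tokenizer import Tokenizer

DEFAULT_INSTRUCTION = "describe the variant :"

# paper-scale query-token counts per modality
FULL_NUM_QUERIES = {"sequence": 32, "gene": 8, "protein": 8}
TINY_NUM_QUERIES = {"sequence": 8, "gene": 4, "protein": 4}


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.05
    warmup_frac: float = 0.1
    clip_norm: float = 1.0
    epochs: int = 15
    batch_size: int = 16
    mixed_precision: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.warmup_frac < 1.0:
            raise ValueError("warmup fraction must lie in (0, 1)")
        if self.clip_norm <= 0:
            raise ValueError("clip norm must be positive")


def tiny_train_config(**overrides) -> TrainConfig:
    """Desk-scale defaults: a full two-stage run finishes in minutes on one CPU."""
    cfg = dict(lr=3e-3, epochs=5, batch_size=16, seed=0)
    cfg.update(overrides)
    return TrainConfig(**cfg)


def build_stage1_models(dims: DimSpec, tokenizer: Tokenizer, rng: np.random.Generator,
                        tiny: bool = True, hidden_dim: int | None = None,
                        num_layers: int | None = None) -> dict[str, QFormer]:
    """One Q-former per modality; tiny profile (d=32, 2 layers) or paper profile."""
    d = hidden_dim if hidden_dim is not None else (32 if tiny else 128)
    layers = num_layers if num_layers is not None else (2 if tiny else 12)
    heads = 4 if tiny else 8
    queries = TINY_NUM_QUERIES if tiny else FULL_NUM_QUERIES
    input_dims = {"sequence": dims.seq_dim, "gene": dims.gene_dim + 2,
                  "protein": dims.protein_dim}
    models = {}
    for mod in MODALITY_ORDER:
        cfg = QFormerConfig(
            input_dim=input_dims[mod], num_layers=layers, hidden_dim=d,
            num_heads=heads, num_queries=queries[mod],
            vocab_size=len(tokenizer), max_text_len=96,
            proj_dim=32 if tiny else 64,
        )
        models[mod] = QFormer(cfg, rng)
    return models


# -- batching -------------------------------------------------------------------


def _pad_embeddings(items: list[VariantItem], modality: str) -> tuple[np.ndarray, np.ndarray]:
    arrs = [it.embeddings[modality].vectors for it in items]
    lengths = np.array([a.shape[0] for a in arrs])
    t = int(lengths.max())
    out = np.zeros((len(arrs), t, arrs[0].shape[1]))
    for i, a in enumerate(arrs):
        out[i, : a.shape[0]] = a
    return out, lengths


def _pad_tokens(seqs: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in seqs])
    t = int(lengths.max())
    out = np.full((len(seqs), t), pad_id, dtype=np.intp)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out, lengths


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n - batch_size + 1, batch_size):
        yield order[lo: lo + batch_size]


def _maybe_downcast(params: list[Tensor], enabled: bool) -> None:
    # reduced-precision mode: gradients are rounded through float32 before the update
    if not enabled:
        return
    for p in params:
        if p.grad is not None:
            p.grad = p.grad.astype(np.float32).astype(np.float64)


# -- Stage 1 ----------------------------------------------------------------------


@dataclass
class Stage1History:
    records: list[dict] = field(default_factory=list)

    def final(self, key: str, modality: str | None = None) -> float:
        recs = self.records if modality is None else [
            r for r in self.records if r.get("modality") == modality
        ]
        return recs[-1][key]

    def series(self, key: str, modality: str) -> list[float]:
        return [r[key] for r in self.records if r.get("modality") == modality]


def _stage1_modality_losses(model: QFormer, emb: np.ndarray, lengths: np.ndarray,
                            ids: np.ndarray, text_lengths: np.ndarray,
                            rng: np.random.Generator) -> tuple[Tensor, Tensor, Tensor]:
    b = emb.shape[0]
    qtok = model.encode(emb, lengths=lengths)
    _, pooled = model.encode_text(ids, lengths=text_lengths)

    itc = model.itc_loss(qtok, pooled)

    with no_grad():
        sims = model.similarity_matrix(qtok.detach(), pooled.detach()).data
    pairs = []
    if b >= 2:
        text_neg, emb_neg = mine_hard_negatives(sims, rng)
        for i in range(b):
            pairs.append((qtok[i: i + 1], list(ids[i]), 1))
            pairs.append((qtok[i: i + 1], list(ids[text_neg[i]]), 0))
            pairs.append((qtok[emb_neg[i]: emb_neg[i] + 1], list(ids[i]), 0))
    else:
        pairs.append((qtok[0:1], list(ids[0]), 1))
    itm = model.itm_loss(pairs)

    itg = model.itg_loss(qtok, ids, lengths=text_lengths)
    return itc, itm, itg


def train_stage1(models: dict[str, QFormer], items: list[VariantItem],
                 tokenizer: Tokenizer, config: TrainConfig,
                 permutation: np.ndarray | None = None) -> Stage1History:
    """Jointly optimize all modality Q-formers on the summed three-part loss.

    ``permutation`` (ablation use) re-pairs item i's embeddings with caption
    ``permutation[i]``; None keeps the true pairing.
    """
    if not items:
        raise ValueError("empty dataset")
    if not models:
        raise ValueError("at least one modality model required")
    rng = np.random.default_rng(config.seed)
    captions = [tokenizer.encode(it.caption) for it in items]
    pairing = np.arange(len(items)) if permutation is None else np.asarray(permutation)

    params = [p for m in models.values() for p in m.parameters()]
    opt = nn.AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    steps_per_epoch = max(1, len(items) // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    history = Stage1History()
    step = 0
    for epoch in range(config.epochs):
        for idx in _batches(len(items), config.batch_size, rng):
            lr = nn.cosine_warmup_lr(step, total_steps, config.lr, config.warmup_frac)
            opt.zero_grad()
            per_modality = []
            record_terms = {}
            for mod, model in models.items():
                emb, lengths = _pad_embeddings([items[i] for i in idx], mod)
                ids, tlen = _pad_tokens([captions[pairing[i]] for i in idx],
                                        tokenizer.pad_id)
                itc, itm, itg = _stage1_modality_losses(model, emb, lengths, ids, tlen, rng)
                per_modality.append((itc, itm, itg))
                record_terms[mod] = (itc.item(), itm.item(), itg.item())
            total = stage1_total_loss(per_modality)
            total.backward()
            _maybe_downcast(params, config.mixed_precision)
            nn.clip_grad_norm(params, config.clip_norm)
            opt.step(lr=lr)
            for mod, (a, b_, c) in record_terms.items():
                history.records.append({
                    "step": step, "epoch": epoch, "modality": mod, "lr": lr,
                    "itc": a, "itm": b_, "itg": c, "total": float(total.item()),
                })
            step += 1
    return history


def in_batch_retrieval_accuracy(model: QFormer, items: list[VariantItem],
                                modality: str, tokenizer: Tokenizer,
                                batch_size: int, seed: int = 0) -> float:
    """Fraction of items whose paired caption wins the in-batch ITC argmax."""
    rng = np.random.default_rng(seed)
    captions = [tokenizer.encode(it.caption) for it in items]
    hits, n = 0, 0
    with no_grad():
        for idx in _batches(len(items), batch_size, rng):
            emb, lengths = _pad_embeddings([items[i] for i in idx], modality)
            ids, tlen = _pad_tokens([captions[i] for i in idx], tokenizer.pad_id)
            qtok = model.encode(emb, lengths=lengths)
            _, pooled = model.encode_text(ids, lengths=tlen)
            sims = model.similarity_matrix(qtok, pooled).data
            hits += int((sims.argmax(axis=1) == np.arange(len(idx))).sum())
            n += len(idx)
    return hits / n


# -- decoder preparation ------------------------------------------------------------


def pretrained_frozen_decoder(captions: list[str], tokenizer: Tokenizer, seed: int = 0,
                              dim: int = 48, num_layers: int = 2, num_heads: int = 4,
                              epochs: int = 30, batch_size: int = 16, lr: float = 3e-3,
                              instruction: str = DEFAULT_INSTRUCTION,
                              max_len: int = 256) -> TinyCausalDecoder:
    """A frozen decoder that already speaks the caption language.

    The tiny decoder is first trained as an unconditional causal LM on
    prompt+caption text (the analogue of the pretrained text backbone), then
    frozen. Stage 2 can only improve on it by injecting variant-specific
    information through the multimodal prefix.
    """
    rng = np.random.default_rng(seed)
    dec = TinyCausalDecoder(rng, vocab_size=len(tokenizer), dim=dim,
                            num_layers=num_layers, num_heads=num_heads, max_len=max_len)
    prompt_ids = tokenizer.encode(instruction, add_special=False)
    seqs = [prompt_ids + tokenizer.encode(c, add_special=False) + [tokenizer.eos_id]
            for c in captions]
    params = dec.parameters()
    opt = nn.AdamW(params, lr=lr, weight_decay=0.01)
    total_steps = epochs * max(1, len(seqs) // batch_size)
    step = 0
    for _ in range(epochs):
        for idx in _batches(len(seqs), batch_size, rng):
            sched = nn.cosine_warmup_lr(step, total_steps, lr)
            opt.zero_grad()
            tok_batch, lengths = _pad_tokens([seqs[i] for i in idx], tokenizer.pad_id)
            labels = tok_batch.copy()
            labels[np.arange(tok_batch.shape[1])[None, :] >= lengths[:, None]] = IGNORE_INDEX
            logits = dec(None, tok_batch)
            loss = masked_ntp_loss(logits, labels)
            loss.backward()
            nn.clip_grad_norm(params, 1.0)
            opt.step(lr=sched)
            step += 1
    dec.freeze()
    return dec


# -- Stage 2 ----------------------------------------------------------------------


class NoMasterAdapter(nn.Module):
    """Master-model ablation: per-modality linear projections whose tokens are
    prepended directly to the decoder prompt (prefix length = sum of K_i)."""

    def __init__(self, rng: np.random.Generator, hidden_dim: int, decoder_dim: int,
                 modalities: tuple[str, ...] = MODALITY_ORDER):
        self.modalities = tuple(modalities)
        self.projections = [nn.Linear(rng, hidden_dim, decoder_dim, bias=False)
                            for _ in self.modalities]

    def fuse(self, modality_tokens: dict[str, Tensor],
             instruction_ids: np.ndarray | None = None) -> MultimodalPrefix:
        from ._tensor import concat

        outs, provenance = [], []
        for mod, proj in zip(self.modalities, self.projections):
            if mod in modality_tokens:
                outs.append(proj(modality_tokens[mod]))
                provenance.append(mod)
        if not outs:
            raise ValueError("no modality tokens provided")
        return MultimodalPrefix(vectors=concat(outs, axis=1), provenance=provenance)


@dataclass
class Stage2History:
    records: list[dict] = field(default_factory=list)
    best_val_ntp: float | None = None


def _stage2_batch(fusion, stage1: dict[str, QFormer], decoder: TinyCausalDecoder,
                  items: list[VariantItem], captions: list[list[int]],
                  idx: np.ndarray, prompt_ids: list[int], pad_id: int) -> Tensor:
    qtoks = {}
    for mod, model in stage1.items():
        emb, lengths = _pad_embeddings([items[i] for i in idx], mod)
        qtoks[mod] = model.encode(emb, lengths=lengths)
    prefix = fusion.fuse(qtoks, instruction_ids=np.asarray(prompt_ids))
    tok_rows, lab_rows = [], []
    for i in idx:
        tokens, labels = assemble_decoder_input(prefix, prompt_ids, captions[i])
        tok_rows.append(list(tokens))
        lab_rows.append(list(labels))
    tok_batch, _ = _pad_tokens(tok_rows, pad_id)
    lab_batch, _ = _pad_tokens(lab_rows, IGNORE_INDEX)
    logits = decoder(prefix.vectors, tok_batch)
    return masked_ntp_loss(logits, lab_batch)


def _decoder_grad_norm(decoder: TinyCausalDecoder) -> float:
    total = 0.0
    for _, t in decoder.named_tensors():
        if t.grad is not None:
            total += float((t.grad ** 2).sum())
    return math.sqrt(total)


def train_stage2(stage1: dict[str, QFormer], fusion, decoder: TinyCausalDecoder,
                 items: list[VariantItem], tokenizer: Tokenizer, config: TrainConfig,
                 instruction: str = DEFAULT_INSTRUCTION,
                 val_items: list[VariantItem] | None = None,
                 stage1_lr_scale: float = 0.1) -> Stage2History:
    """Next-token training of fusion + projections + Stage-1 models with the
    decoder frozen. Rejects an unfrozen decoder before taking any step.

    With ``val_items`` given, an epoch-level checkpoint of all trainable
    modules is kept and the epoch with the lowest validation NTP loss is
    restored at the end (best-by-validation selection).
    """
    if not decoder.frozen:
        raise ValueError("decoder must be frozen before Stage-2 training")
    if not items:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    captions = [tokenizer.encode(it.caption, add_special=False) + [tokenizer.eos_id]
                for it in items]
    prompt_ids = tokenizer.encode(instruction, add_special=False)

    stage1_params = [p for m in stage1.values() for p in m.parameters()]
    fusion_params = fusion.parameters()
    params = stage1_params + fusion_params
    # discriminative learning rates: freshly initialised fusion modules train at
    # the full rate, already-aligned Stage-1 models at a fraction of it
    opt_fusion = nn.AdamW(fusion_params, lr=config.lr, weight_decay=config.weight_decay)
    opt_stage1 = nn.AdamW(stage1_params, lr=config.lr * stage1_lr_scale,
                          weight_decay=config.weight_decay)
    steps_per_epoch = max(1, len(items) // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    history = Stage2History()
    best = None  # (val_loss, state dicts)
    step = 0
    for epoch in range(config.epochs):
        for idx in _batches(len(items), config.batch_size, rng):
            lr = nn.cosine_warmup_lr(step, total_steps, config.lr, config.warmup_frac)
            opt_fusion.zero_grad()
            opt_stage1.zero_grad()
            loss = _stage2_batch(fusion, stage1, decoder, items, captions, idx,
                                 prompt_ids, tokenizer.pad_id)
            loss.backward()
            _maybe_downcast(params, config.mixed_precision)
            nn.clip_grad_norm(params, config.clip_norm)
            opt_fusion.step(lr=lr)
            opt_stage1.step(lr=lr * stage1_lr_scale)
            history.records.append({
                "step": step, "epoch": epoch, "lr": lr, "ntp": float(loss.item()),
                "decoder_grad_norm": _decoder_grad_norm(decoder),
            })
            step += 1
        if val_items is not None:
            val_loss = stage2_validation_loss(stage1, fusion, decoder, val_items,
                                              tokenizer, instruction=instruction)
            history.records[-1]["val_ntp"] = val_loss
            if best is None or val_loss < best[0]:
                best = (val_loss,
                        {m: q.state_dict() for m, q in stage1.items()},
                        fusion.state_dict())
    if best is not None:
        for m, q in stage1.items():
            q.load_state_dict(best[1][m])
        fusion.load_state_dict(best[2])
        history.best_val_ntp = best[0]
    return history


def stage2_validation_loss(stage1: dict[str, QFormer], fusion,
                           decoder: TinyCausalDecoder, items: list[VariantItem],
                           tokenizer: Tokenizer,
                           instruction: str = DEFAULT_INSTRUCTION) -> float:
    captions = [tokenizer.encode(it.caption, add_special=False) + [tokenizer.eos_id]
                for it in items]
    prompt_ids = tokenizer.encode(instruction, add_special=False)
    total, batches = 0.0, 0
    with no_grad():
        for lo in range(0, len(items), 16):
            idx = np.arange(lo, min(lo + 16, len(items)))
            loss = _stage2_batch(fusion, stage1, decoder, items, captions, idx,
                                 prompt_ids, tokenizer.pad_id)
            total += float(loss.item())
            batches += 1
    return total / batches


def answer_token_accuracy(stage1: dict[str, QFormer], fusion, decoder: TinyCausalDecoder,
                          items: list[VariantItem], tokenizer: Tokenizer,
                          instruction: str = DEFAULT_INSTRUCTION) -> float:
    """Teacher-forced accuracy of the decoder's argmax on answer tokens."""
    captions = [tokenizer.encode(it.caption, add_special=False) + [tokenizer.eos_id]
                for it in items]
    prompt_ids = tokenizer.encode(instruction, add_special=False)
    hits, total = 0, 0
    with no_grad():
        for chunk in range(0, len(items), 16):
            idx = np.arange(chunk, min(chunk + 16, len(items)))
            qtoks = {}
            for mod, model in stage1.items():
                emb, lengths = _pad_embeddings([items[i] for i in idx], mod)
                qtoks[mod] = model.encode(emb, lengths=lengths)
            prefix = fusion.fuse(qtoks, instruction_ids=np.asarray(prompt_ids))
            rows = [assemble_decoder_input(prefix, prompt_ids, captions[i]) for i in idx]
            tok_batch, _ = _pad_tokens([list(t) for t, _ in rows], tokenizer.pad_id)
            lab_batch, _ = _pad_tokens([list(l) for _, l in rows], IGNORE_INDEX)
            logits = decoder(prefix.vectors, tok_batch)
            pred = logits.data[:, :-1, :].argmax(axis=-1)
            lab = lab_batch[:, 1:]
            keep = lab != IGNORE_INDEX
            hits += int((pred[keep] == lab[keep]).sum())
            total += int(keep.sum())
    return hits / total


def majority_token_baseline(items: list[VariantItem], tokenizer: Tokenizer) -> float:
    """Accuracy of always predicting the single most frequent answer token."""
    counts: dict[int, int] = {}
    total = 0
    for it in items:
        for t in tokenizer.encode(it.caption, add_special=False) + [tokenizer.eos_id]:
            counts[t] = counts.get(t, 0) + 1
            total += 1
    return max(counts.values()) / total


def generate_captions(stage1: dict[str, QFormer], fusion, decoder: TinyCausalDecoder,
                      items: list[VariantItem], tokenizer: Tokenizer,
                      instruction: str = DEFAULT_INSTRUCTION,
                      max_new_tokens: int = 72) -> list[str]:
    """Greedy-decode one caption per item from its multimodal prefix."""
    prompt_ids = tokenizer.encode(instruction, add_special=False)
    out = []
    with no_grad():
        for it in items:
            qtoks = {}
            for mod, model in stage1.items():
                vec = it.embeddings[mod].vectors
                qtoks[mod] = model.encode(vec[None, :, :])
            prefix = fusion.fuse(qtoks, instruction_ids=np.asarray(prompt_ids))
            ids = decoder.greedy_decode(prefix.vectors, prompt_ids, max_new_tokens,
                                        eos_id=tokenizer.eos_id)
            out.append(tokenizer.decode(ids))
    return out


# -- ablations --------------------------------------------------------------------


def derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform-ish permutation with no fixed points (rejection sampling)."""
    if n < 2:
        raise ValueError("derangement requires n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


@dataclass
class PermutationAblationResult:
    aligned_history: Stage1History
    permuted_history: Stage1History
    aligned_retrieval: dict[str, float]
    permuted_retrieval: dict[str, float]
    permutation: np.ndarray
    batch_size: int

    def itc_series(self, which: str, modality: str) -> list[float]:
        hist = self.aligned_history if which == "aligned" else self.permuted_history
        return hist.series("itc", modality)


def permutation_ablation(items: list[VariantItem], tokenizer: Tokenizer,
                         config: TrainConfig, dims: DimSpec,
                         seed: int = 0) -> PermutationAblationResult:
    """Train Stage 1 twice from identical initialisation: once with true
    embedding-caption pairing, once with captions deranged across items."""
    if len({it.caption for it in items}) < 2:
        raise ValueError("permutation ablation needs at least two distinct captions")
    rng = np.random.default_rng(seed)
    perm = derangement(len(items), rng)

    def fresh_models() -> dict[str, QFormer]:
        return build_stage1_models(dims, tokenizer, np.random.default_rng(seed), tiny=True)

    aligned_models = fresh_models()
    aligned_hist = train_stage1(aligned_models, items, tokenizer, config)
    permuted_models = fresh_models()
    permuted_hist = train_stage1(permuted_models, items, tokenizer, config,
                                 permutation=perm)

    aligned_ret, permuted_ret = {}, {}
    for mod in aligned_models:
        aligned_ret[mod] = in_batch_retrieval_accuracy(
            aligned_models[mod], items, mod, tokenizer, config.batch_size, seed=seed)
        permuted_ret[mod] = in_batch_retrieval_accuracy(
            permuted_models[mod], items, mod, tokenizer, config.batch_size, seed=seed)
    return PermutationAblationResult(
        aligned_history=aligned_hist, permuted_history=permuted_hist,
        aligned_retrieval=aligned_ret, permuted_retrieval=permuted_ret,
        permutation=perm, batch_size=config.batch_size,
    )


@dataclass
class MasterAblationReport:
    with_master: FieldReport
    no_master: FieldReport
    with_master_prefix_len: int
    no_master_prefix_len: int


def _clone_stage1(models: dict[str, QFormer], tokenizer: Tokenizer) -> dict[str, QFormer]:
    out = {}
    for mod, m in models.items():
        clone = QFormer(copy.deepcopy(m.config), np.random.default_rng(0))
        clone.load_state_dict(m.state_dict())
        out[mod] = clone
    return out


def master_ablation(items: list[VariantItem], tokenizer: Tokenizer, dims: DimSpec,
                    stage1_config: TrainConfig, stage2_config: TrainConfig,
                    eval_items: list[VariantItem], decoder_seed: int = 0,
                    decoder_dim: int = 48,
                    val_items: list[VariantItem] | None = None) -> MasterAblationReport:
    """Paired comparison: instruction-conditioned fusion vs direct prepending of
    per-modality projected tokens, trained with identical seeds and epochs
    (best-by-validation selection when ``val_items`` is given) and evaluated
    per caption field on the same held-out items."""
    rng_seed = stage2_config.seed
    stage1 = build_stage1_models(dims, tokenizer, np.random.default_rng(rng_seed), tiny=True)
    train_stage1(stage1, items, tokenizer, stage1_config)

    decoder = pretrained_frozen_decoder([it.caption for it in items], tokenizer,
                                        seed=decoder_seed, dim=decoder_dim)
    d_q = next(iter(stage1.values())).config.hidden_dim

    # with master
    stage1_a = _clone_stage1(stage1, tokenizer)
    master = MasterQFormer(
        MasterConfig(decoder_dim=decoder.embedding_dim, num_layers=4,
                     num_meta_queries=16, hidden_dim=d_q, num_heads=4,
                     instr_vocab_size=len(tokenizer)),
        np.random.default_rng(rng_seed),
    )
    train_stage2(stage1_a, master, decoder, items, tokenizer, stage2_config,
                 val_items=val_items)
    preds_a = generate_captions(stage1_a, master, decoder, eval_items, tokenizer)

    # without master
    stage1_b = _clone_stage1(stage1, tokenizer)
    adapter = NoMasterAdapter(np.random.default_rng(rng_seed), d_q, decoder.embedding_dim)
    train_stage2(stage1_b, adapter, decoder, items, tokenizer, stage2_config,
                 val_items=val_items)
    preds_b = generate_captions(stage1_b, adapter, decoder, eval_items, tokenizer)

    gold = [it.caption for it in eval_items]
    with_prefix = master.config.num_meta_queries
    no_prefix = sum(m.config.num_queries for m in stage1_b.values())
    return MasterAblationReport(
        with_master=per_field_accuracy(preds_a, gold),
        no_master=per_field_accuracy(preds_b, gold),
        with_master_prefix_len=with_prefix,
        no_master_prefix_len=no_prefix,
    )


def config_to_dict(config) -> dict:
    return asdict(config)
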