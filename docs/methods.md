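# Methods

## Model

### Modality Q-formers (Stage 1)

Each modality owns a querying transformer: K learnable query vectors
(initialised N(0, 0.02²)) pass through pre-LN transformer blocks that
self-attend among the queries and cross-attend to the (linearly projected)
modality embedding at every `cross_attn_period`-th layer, starting at layer 0
(0-based even layers with the default period of 2). The output is always
exactly K vectors of width d_q, independent of input length. Paper-scale
defaults: 12 layers, d_q = 128, 8 heads, feed-forward width 4·d_q, K = 32 for
the sequence modality and 8 for gene and protein.

The text side shares the Q-former's transformer blocks (one parameter set,
task-dependent masks): bidirectional self-attention for text encoding
(ITC/ITM), causal for grounded generation (ITG). Pooling for the contrastive
text projection is a length-weighted mean over valid token positions.

Loss details:

* **ITC.** Similarity between item i's query tokens and caption j is the
  maximum over the K tokens of the cosine between the projected query and the
  projected pooled text (projections are separate linear heads into a shared
  space, ℓ2-normalised). The loss is the symmetric InfoNCE averaged over both
  softmax directions. The temperature is stored as log τ and initialised so
  that 1/τ = 14.3. Max-pooling over queries is configurable in the sense that
  the similarity matrix is exposed as its own method.
* **ITM.** For each batch item: one positive pair plus one text-negative and
  one embedding-negative mined from the detached ITC similarity matrix, each
  sampled with probability proportional to the off-diagonal softmax of its
  row/column (the diagonal is excluded; a batch of one yields no negatives
  and a warning). Query tokens attend to the caption embeddings, are
  mean-pooled, and a two-way head is scored with cross-entropy — closed forms:
  ln 2 at zero logits, → 0 at saturation.
* **ITG.** Mean per-token causal cross-entropy of the caption with the query
  tokens prepended as attention keys/values visible to all text positions;
  text self-attention is causally masked. Uniform logits give ln V exactly.

The Stage-1 objective is the plain unweighted sum of the three terms over all
modalities; all modality Q-formers are optimised jointly by one schedule.

### Master Q-former (Stage 2)

The fusion model holds N_m = 32 meta-queries (paper scale; 16 in the tiny
profile). Meta-queries and the embedded instruction form one self-attention
sequence; cross-attention — at every second layer, over the Stage-1 tokens of
all provided modalities concatenated in fixed order (sequence, gene,
protein) — updates only the meta-query positions, and a dedicated LayerNorm
is applied to the Stage-1 tokens before every cross-attention. Only the
meta-query positions are emitted and projected by W_proj (no bias) into the
decoder's embedding space, so the prefix length is always N_m regardless of
the modality subset or instruction length. Instructions use the master's own
embedding table, not the decoder's. Paper-scale master depth is 6 layers; the
tiny profile uses 4 so that cross-attention still fires twice.

### Frozen decoder and Stage-2 training

Decoder input order is prefix ∥ prompt ∥ answer; every prefix and prompt
position carries the ignore label −100 and only answer positions contribute
to the next-token loss. Two decoder stand-ins are provided:

* `tiny_frozen_decoder` — fixed random weights determined by a seed; used for
  the shape, determinism, and frozen-contract checks.
* `pretrained_frozen_decoder` — the same architecture first trained as an
  unconditional causal LM on prompt+caption text, then frozen. This is the
  stand-in used for Stage-2 experiments: like a pretrained language model it
  already generates fluent caption JSON unconditionally, and the multimodal
  prefix must inject the variant-specific content. A random decoder is not
  steerable to structured output at this scale.

Stage 2 rejects an unfrozen decoder before taking any step, and the decoder's
parameters are excluded from the gradient graph entirely: its recorded
gradient norm is 0.0 at every step and its weight checksum is bitwise
unchanged after training.

## Optimization

AdamW (β = 0.9/0.999, decoupled weight decay 0.05), cosine decay with linear
warmup over 10% of total steps (lr exactly 0 at step 0 and the base rate at
the end of warmup), gradient clipping at global norm 1.0. Paper-scale base lr
is 10⁻⁴ over 15 epochs; the desk-scale profile (`tiny_train_config`) uses
3·10⁻³, d_q = 32, 2 layers, batch 16, and ≤5 Stage-1 epochs so a full
two-stage run finishes in minutes on one CPU.

Stage 2 uses discriminative learning rates: freshly initialised fusion
modules (master or the no-master projections) train at the full rate while
the already-aligned Stage-1 Q-formers train at 0.1× it. This protects the
Stage-1 alignment from being overwritten by the next-token gradient and is
applied identically to both ablation variants. When a validation split is
supplied, an epoch-level checkpoint of all trainable modules is kept and the
epoch with the lowest validation next-token loss is restored at the end.

The `mixed_precision` flag rounds gradients through half precision before
the update; it is off by default so every run is bitwise reproducible from
its seed. All computation is float32 by default; the autodiff engine can be
switched to float64 (`set_default_dtype`) and the finite-difference gradient
checks in the test suite do so.

## Synthetic data

Every generated variant is driven by a discrete latent code: chromosome
(1–22, X), coding/noncoding status (35% coding), most severe consequence
(consistent with the coding flag; three coding and four noncoding labels),
3–5 neighborhood gene ids from a 24-gene pool, and 1–2 cell types from a pool
of 8. Captions derive deterministically from the code and are serialized as
compact JSON with a fixed field order (chromosome, variant_type, consequence,
nearest_genes, cell_types); values are single word-tokens so a
whitespace/punctuation tokenizer round-trips captions exactly.

Each modality embedding is a noisy fixed linear image of a masked one-hot
encoding of the latent (σ = 0.1 by default, maps drawn once per dataset
seed):

* **sequence** — 2B rows (interleaved ref/alt bins, B = 8 by default, 24
  dims) seeing chromosome, type, consequence, and cell types;
* **gene** — one row per neighborhood gene (a per-gene embedding table entry
  plus noise) with two appended feature columns, log-distance ln(1 + bp) and
  an overlap flag; this is the only modality carrying gene identities, which
  is what makes the fusion ablation informative;
* **protein** — two rows (ref, alt) seeing type and consequence only.

The neighborhood sizes and caption lengths are chosen so the whole pipeline
is realistic in structure (multi-gene neighborhoods, multi-token captions)
while keeping attention windows small. What the generator does **not**
emulate: real sequence content, linkage structure, QTL/colocalisation
statistics, alias ambiguity in gene symbols, and class imbalance beyond the
coding fraction. Passing tests therefore demonstrate that the architecture
and losses recover plantable cross-modal signal — not that the model works on
real variant data.

Target-gene traces place the annotated target at the closest gene except for
an exactly-controlled fraction of traces (`round(n·frac)`), which supports
the closest-gene baseline and its non-closest stratum. Prioritization groups
contain locus-matched candidate ids with exactly one causal label each.

## Caption pipeline conventions

Variant ids are `chrom_pos_ref_alt` with 1-based positions; a leading `chr`
is stripped on parsing. Gene annotations use half-open 0-based intervals
(BED); the distance from a variant to a gene is the minimal bp gap to the
interval (0 inside), log-distance is ln(1 + distance), and strand is ignored.
Neighborhoods rank genes by that distance with ties broken by ascending
interval start then lexicographic id, capped at 15 genes; no padding rows are
emitted (the embedding assembler pads). The genome-build agreement filter
keeps a variant iff two independent closest-gene calls agree after
normalisation (reason codes: ok / mismatch / missing_id). Track selection
keeps the k = 5 tracks of largest absolute effect size, ties by track id.

## Evaluation

Per-field scoring: chromosome, variant type, and consequence by normalized
exact match; nearest genes by nonempty set intersection (exact set equality
available as a strict mode); cell types by ROUGE-L F1 (longest common
subsequence over word tokens), computed in-package. An unparseable predicted
caption scores 0 on every field but still counts in n.

Prioritization: the rank of the causal candidate is its 1-based position in
the ranked list (candidates missing from a ranking are appended in input
order); Top-k is the fraction of groups with rank ≤ k; the rank spread is the
population standard deviation, matching the closed form √((n²−1)/12) for a
uniformly random rank (2.87 at n = 10). Ranked lists can be extracted from
generated text by first-occurrence order of candidate ids.

## Ablations

* **Permutation control.** Stage 1 is trained twice from identical
  initialisation — once with true pairing, once with captions deranged
  across items (no fixed points). The aligned run must retrieve far above
  chance while the permuted run's retrieval stays at chance and its
  contrastive loss flatlines above the aligned run's.
* **Master removal.** The fusion model is replaced by per-modality linear
  projections whose tokens are prepended directly to the decoder prompt
  (prefix length Σ Kᵢ = 48 at paper scale vs 32 with the master). Both
  variants start from the same Stage-1 snapshot and train with identical
  seeds, epochs, and schedules; per-field reports are computed by greedy
  decoding on the same held-out items.

## Problem sizes used by the test suite

Alignment recovery and the permutation control use 512 variants, batch 16,
4 epochs of the tiny profile. The fusion ablation uses 5 replicates of 128
training / 24 validation / 48 held-out variants with 3 Stage-1 and 40 Stage-2
epochs. The frozen-decoder conservation run uses 96 variants and 15 Stage-2
epochs. These sizes make the full suite complete in well under half an hour
on a single CPU while keeping every statistical margin comfortable.

## Known limitations

* The autodiff engine is eager and unfused beyond softmax/GELU/LayerNorm;
  it is adequate for desk-scale models only.
* The tokenizer assumes caption values contain no internal whitespace;
  attaching a real decoder implies using its tokenizer instead.
* Hard-negative mining samples from the full softmax over off-diagonal
  similarities rather than a top-k pool.
* The gene-field advantage of the fusion model over direct token prepending
  is a small-sample comparison at desk scale (48 held-out items per
  replicate); it is directional, not a calibrated effect-size estimate.
* Consequence labels are inputs, not predictions from sequence; no live
  annotation services are queried.
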