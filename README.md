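# varfuse

Hierarchical querying-transformer fusion of multimodal genomic-variant
embeddings with a frozen text decoder.

## The problem

Interpreting a single-nucleotide variant (SNV) means integrating evidence at
several biological scales: the local DNA sequence context of the ref and alt
alleles, the neighborhood of nearby protein-coding genes, and the protein
consequence of the change. Modern biological foundation models produce rich
embeddings at each of these scales, but text-based reasoning models cannot
consume them directly, and fine-tuning a language model per task discards its
general reasoning ability.

`varfuse` implements an architecture that bridges the two without ever
training the language model:

1. **Modality Q-formers (Stage 1).** A querying transformer (Q-former)
   distills a variable-length modality embedding into K learned query vectors
   q₁…q_K via cross-attention. One Q-former per modality (sequence: K=32,
   gene neighborhood: K=8, protein: K=8 at paper scale) is aligned with
   structured JSON variant captions through three losses, summed without
   weights over the N modalities, L = Σᵢ L_ITC(i) + L_ITM(i) + L_ITG(i):
   - **ITC** (contrastive): symmetric InfoNCE between ℓ2-normalised query and
     pooled-text projections q̂, t̂ with learnable temperature τ,
     −½ E[log (exp(q̂ᵀt̂/τ) / Σⱼ exp(q̂ᵀt̂ⱼ/τ)) + log (exp(t̂ᵀq̂/τ) / Σⱼ exp(t̂ᵀq̂ⱼ/τ))];
     per-pair similarity is the max over the K query tokens.
   - **ITM** (matching): binary classification of (query tokens, caption)
     pairs, with hard negatives sampled proportionally to the in-batch ITC
     similarities.
   - **ITG** (grounded generation): causal language modeling of the caption
     with the query tokens visible to every text position as a soft prompt.
2. **Master Q-former (Stage 2).** N_m = 32 meta-query vectors self-attend
   together with a tokenised instruction and cross-attend — every second
   layer — to the layer-normalised concatenation of all Stage-1 query tokens.
   The emitted meta-queries pass through a projection W_proj into the frozen
   decoder's token-embedding space, forming a fixed 32-vector multimodal
   prefix.
3. **Frozen decoder.** Next-token loss on the answer tokens only (prompt and
   prefix positions carry the −100 ignore label) backpropagates through the
   decoder into W_proj, the master, and the Stage-1 Q-formers. The decoder's
   weights receive no gradient at any point.

Everything runs at desk scale on one CPU: a synthetic generator produces
latent-linked embeddings and captions for all three modalities, and a tiny
causal decoder (optionally pretrained on the caption language, then frozen)
stands in for the language model. Evaluation covers per-field annotation
accuracy, target-gene identification with a closest-gene baseline and its
non-closest stratum, and grouped causal-variant prioritization (Top-k
accuracy, mean rank ± population stdev).

## Worked example

Train the three modality Q-formers on synthetic aligned data and measure
in-batch retrieval (does each embedding's query representation pick out its
own caption from the batch?):

```python
import numpy as np
from varfuse import DimSpec, Tokenizer, gen_variant_dataset, random_ranking_reference
from varfuse.training import (build_stage1_models, train_stage1,
                              tiny_train_config, in_batch_retrieval_accuracy)

dims = DimSpec()
items = gen_variant_dataset(256, seed=7, dims=dims)
print(items[0].caption)
tok = Tokenizer.from_corpus([it.caption for it in items])
models = build_stage1_models(dims, tok, np.random.default_rng(0))
train_stage1(models, items, tok, tiny_train_config(epochs=4))
for mod, model in models.items():
    acc = in_batch_retrieval_accuracy(model, items, mod, tok, batch_size=16)
    print(f"{mod:9s} in-batch retrieval: {acc:.3f}  (chance 0.0625)")

ref = random_ranking_reference(10)
print(f"random reference: top-k {ref.top_k}, mean rank {ref.mean_rank}, "
      f"stdev {ref.std_rank:.2f}")
```

Output:

```
{"chromosome":"15","variant_type":"coding","consequence":"synonymous_variant","nearest_genes":["G14","G16","G21"],"cell_types":["CT2","CT3"]}
sequence  in-batch retrieval: 0.473  (chance 0.0625)
gene      in-batch retrieval: 0.367  (chance 0.0625)
protein   in-batch retrieval: 0.426  (chance 0.0625)
random reference: top-k {1: 0.1, 2: 0.2, 3: 0.3}, mean rank 5.5, stdev 2.87
```

After four epochs of the three-loss alignment, every modality retrieves its
paired caption six to eight times more often than the 1/16 chance level of a
16-item batch. The last line is the analytic reference for a causal variant
ranked uniformly at random within a 10-candidate group: Top-k = k/n, mean
rank (n+1)/2 = 5.5, population stdev √((n²−1)/12) ≈ 2.87.

A command-line surface wraps the same calls:

```bash
varfuse train-stage1 --n 256 --seed 0 --out runs/stage1
varfuse train-stage2 --n 256 --seed 0 --out runs/stage2
varfuse ablate --permute --n 192 --out runs/perm
varfuse ablate --no-master --n 128 --out runs/nomaster
```

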