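"""Latent-linked synthetic multimodal variant data.

Every generator here is driven by a single discrete latent code per variant
(chromosome, coding status, consequence, gene neighborhood, cell types).
Each modality embedding is a noisy fixed linear image of (part of) the
one-hot encoded latent, so embedding and caption share mutual information
and cross-modal alignment is learnable by construction:

* **sequence** modality (2B interleaved ref/alt bins) carries chromosome,
  variant type, consequence, and cell types;
* **gene** modality (one row per neighborhood gene, plus log-distance and
  overlap columns) is the only modality that carries the gene identities;
* **protein** modality (one ref row, one alt row) carries variant type and
  consequence.

Captions derive deterministically from the latent code, so a model can only
predict the gene field by reading the gene modality — the property the
fusion ablation relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .captions import (
    GeneNeighborhood,
    NeighborGene,
    VariantRecord,
    build_caption,
    write_bed,
)
from .decoder import TinyCausalDecoder

CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X"]
CODING_CONSEQUENCES = ["missense_variant", "synonymous_variant", "stop_gained"]
NONCODING_CONSEQUENCES = [
    "intron_variant",
    "intergenic_variant",
    "upstream_gene_variant",
    "regulatory_region_variant",
]
CONSEQUENCES = CODING_CONSEQUENCES + NONCODING_CONSEQUENCES
GENE_POOL = [f"G{i:02d}" for i in range(24)]
CELL_TYPE_POOL = [f"CT{i}" for i in range(8)]
BASES = "ACGT"

CODING_FRACTION = 0.35  # SNV sets skew noncoding; regulatory variants dominate


@dataclass
class LatentVariantCode:
    """The discrete ground truth behind one synthetic variant."""

    chromosome_label: str
    variant_type: str
    consequence_label: str
    gene_ids: list[str]
    cell_type_labels: list[str]
    seed: int

    def __post_init__(self):
        coding = self.consequence_label in CODING_CONSEQUENCES
        if (self.variant_type == "coding") != coding:
            raise ValueError(
                f"consequence {self.consequence_label} inconsistent with "
                f"variant_type {self.variant_type}"
            )

    def one_hot(self) -> np.ndarray:
        """Concatenated one-/multi-hot blocks: chromosome, type, consequence, genes, cells."""
        z = np.zeros(latent_dim())
        off = 0
        z[off + CHROMOSOMES.index(self.chromosome_label)] = 1.0
        off += len(CHROMOSOMES)
        z[off + (0 if self.variant_type == "coding" else 1)] = 1.0
        off += 2
        z[off + CONSEQUENCES.index(self.consequence_label)] = 1.0
        off += len(CONSEQUENCES)
        for g in self.gene_ids:
            z[off + GENE_POOL.index(g)] = 1.0
        off += len(GENE_POOL)
        for c in self.cell_type_labels:
            z[off + CELL_TYPE_POOL.index(c)] = 1.0
        return z


def latent_dim() -> int:
    return len(CHROMOSOMES) + 2 + len(CONSEQUENCES) + len(GENE_POOL) + len(CELL_TYPE_POOL)


# slices of the latent vector visible to each modality
def _latent_mask(modality: str) -> np.ndarray:
    n_chrom, n_cons = len(CHROMOSOMES), len(CONSEQUENCES)
    n_gene, n_cell = len(GENE_POOL), len(CELL_TYPE_POOL)
    m = np.zeros(latent_dim())
    chrom = slice(0, n_chrom)
    vtype = slice(n_chrom, n_chrom + 2)
    cons = slice(n_chrom + 2, n_chrom + 2 + n_cons)
    cells = slice(n_chrom + 2 + n_cons + n_gene, latent_dim())
    if modality == "sequence":
        for s in (chrom, vtype, cons, cells):
            m[s] = 1.0
    elif modality == "protein":
        for s in (vtype, cons):
            m[s] = 1.0
    else:
        raise ValueError(modality)
    return m


@dataclass
class SyntheticGenome:
    """Small genome: chromosome lengths and half-open gene intervals."""

    chrom_lengths: dict[str, int]
    gene_intervals: dict[str, list[tuple[str, int, int, str]]]

    def __post_init__(self):
        seen: set[str] = set()
        for chrom, genes in self.gene_intervals.items():
            length = self.chrom_lengths[chrom]
            for gid, start, end, _ in genes:
                if gid in seen:
                    raise ValueError(f"duplicate gene id {gid}")
                seen.add(gid)
                if not (0 <= start < end <= length):
                    raise ValueError(f"{gid}: interval [{start},{end}) outside [0,{length})")

    def to_bed(self, path) -> None:
        rows = [
            (chrom, start, end, gid, 0, strand)
            for chrom, genes in sorted(self.gene_intervals.items())
            for gid, start, end, strand in genes
        ]
        write_bed(rows, path)


def gen_synthetic_genome(rng: np.random.Generator, n_chroms: int = 3,
                         genes_per_chrom: int = 8,
                         chrom_length: int = 1_000_000) -> SyntheticGenome:
    chroms = CHROMOSOMES[:n_chroms]
    intervals: dict[str, list[tuple[str, int, int, str]]] = {}
    gid = 0
    for chrom in chroms:
        genes = []
        cursor = 0
        for _ in range(genes_per_chrom):
            gap = int(rng.integers(5_000, 40_000))
            length = int(rng.integers(2_000, 30_000))
            start = cursor + gap
            end = min(start + length, chrom_length - 1)
            if start >= end:
                break
            genes.append((f"SG{gid:03d}", start, end, rng.choice(["+", "-"])))
            gid += 1
            cursor = end
        intervals[chrom] = genes
    return SyntheticGenome(chrom_lengths={c: chrom_length for c in chroms},
                           gene_intervals=intervals)


@dataclass
class ModalityEmbedding:
    """Variable-length sequence of fixed-dimension vectors tagged by modality."""

    modality: str
    vectors: np.ndarray  # (T, D)

    @property
    def length(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class DimSpec:
    """Per-modality embedding sizes. ``gene_dim`` excludes the two appended
    feature columns (log-distance, overlap flag)."""

    seq_bins: int = 8        # B; the sequence modality has length 2B
    seq_dim: int = 24
    gene_dim: int = 16
    protein_dim: int = 20

    def validate(self) -> None:
        for name in ("seq_bins", "seq_dim", "gene_dim", "protein_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class VariantItem:
    record: VariantRecord
    latent: LatentVariantCode
    embeddings: dict[str, ModalityEmbedding]
    caption: str


def _draw_latent(rng: np.random.Generator, seed: int) -> LatentVariantCode:
    coding = rng.random() < CODING_FRACTION
    cons = rng.choice(CODING_CONSEQUENCES if coding else NONCODING_CONSEQUENCES)
    n_genes = int(rng.integers(3, 6))
    genes = list(rng.choice(GENE_POOL, size=n_genes, replace=False))
    n_cells = int(rng.integers(1, 3))
    cells = sorted(rng.choice(CELL_TYPE_POOL, size=n_cells, replace=False))
    return LatentVariantCode(
        chromosome_label=str(rng.choice(CHROMOSOMES)),
        variant_type="coding" if coding else "noncoding",
        consequence_label=str(cons),
        gene_ids=[str(g) for g in genes],
        cell_type_labels=[str(c) for c in cells],
        seed=seed,
    )


def gen_variant_dataset(n: int, seed: int, dims: DimSpec | None = None,
                        noise_sigma: float = 0.1) -> list[VariantItem]:
    """Generate ``n`` latent-linked (record, embeddings, caption) items.

    The maps from one-hot latent to each modality are fixed random linears
    drawn once from ``seed``, then shared across all items; each embedding row
    adds independent N(0, ``noise_sigma``²) noise.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    dims = dims or DimSpec()
    dims.validate()
    rng = np.random.default_rng(seed)
    zdim = latent_dim()
    scale = 1.0 / math.sqrt(zdim)
    a_seq = rng.normal(0, scale, size=(dims.seq_dim, zdim))
    a_prot = rng.normal(0, scale, size=(dims.protein_dim, zdim))
    gene_table = rng.normal(0, 1.0, size=(len(GENE_POOL), dims.gene_dim))
    seq_pos = rng.normal(0, 0.05, size=(2 * dims.seq_bins, dims.seq_dim))
    prot_role = rng.normal(0, 0.05, size=(2, dims.protein_dim))
    seq_mask = _latent_mask("sequence")
    prot_mask = _latent_mask("protein")

    items: list[VariantItem] = []
    for i in range(n):
        latent = _draw_latent(rng, seed=i)
        z = latent.one_hot()

        seq = (a_seq @ (z * seq_mask))[None, :] + seq_pos
        seq = seq + rng.normal(0, noise_sigma, size=seq.shape)

        dists = np.sort(rng.integers(0, 200_000, size=len(latent.gene_ids)))
        dists[0] = int(rng.integers(0, 2)) * dists[0]  # closest gene may overlap
        gene_rows = []
        for gid, dist in zip(latent.gene_ids, dists):
            base = gene_table[GENE_POOL.index(gid)] + rng.normal(0, noise_sigma, size=dims.gene_dim)
            gene_rows.append(np.concatenate([base, [math.log1p(int(dist)), float(dist == 0)]]))
        gene = np.asarray(gene_rows)

        prot = (a_prot @ (z * prot_mask))[None, :] + prot_role
        prot = prot + rng.normal(0, noise_sigma, size=prot.shape)

        chrom_len = 1_000_000
        pos = int(rng.integers(1, chrom_len))
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        record = VariantRecord(
            chromosome=latent.chromosome_label,
            position=pos,
            ref=str(ref),
            alt=str(alt),
            variant_type=latent.variant_type,
            consequence=latent.consequence_label,
            nearest_genes=list(latent.gene_ids),
            cell_types=list(latent.cell_type_labels),
        )
        items.append(
            VariantItem(
                record=record,
                latent=latent,
                embeddings={
                    "sequence": ModalityEmbedding("sequence", seq),
                    "gene": ModalityEmbedding("gene", gene),
                    "protein": ModalityEmbedding("protein", prot),
                },
                caption=build_caption(record),
            )
        )
    return items


@dataclass
class TargetGeneTrace:
    """A variant linked to a disease with one annotated target gene."""

    variant_id: str
    disease: str
    neighborhood: GeneNeighborhood
    target_gene: str

    @property
    def closest_gene(self) -> str | None:
        g = self.neighborhood.closest
        return g.gene_id if g else None


def gen_target_gene_traces(n: int, frac_non_closest: float, seed: int) -> list[TargetGeneTrace]:
    """Traces where exactly ``round(n * frac_non_closest)`` targets are not the closest gene."""
    if not 0.0 <= frac_non_closest <= 1.0:
        raise ValueError(f"frac_non_closest must be in [0,1], got {frac_non_closest}")
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    rng = np.random.default_rng(seed)
    n_non_closest = round(n * frac_non_closest)
    flags = np.zeros(n, dtype=bool)
    flags[:n_non_closest] = True
    rng.shuffle(flags)
    traces = []
    for i, non_closest in enumerate(flags):
        n_genes = int(rng.integers(3, 9))
        dists = np.sort(rng.choice(np.arange(0, 500_000), size=n_genes, replace=False))
        gids = [f"TG{i:03d}_{j}" for j in range(n_genes)]
        genes = [
            NeighborGene(gene_id=g, distance=int(d), overlaps=(int(d) == 0))
            for g, d in zip(gids, dists)
        ]
        target = gids[int(rng.integers(1, n_genes))] if non_closest else gids[0]
        chrom = str(rng.choice(CHROMOSOMES))
        pos = int(rng.integers(1, 1_000_000))
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        traces.append(
            TargetGeneTrace(
                variant_id=f"{chrom}_{pos}_{ref}_{alt}",
                disease=f"trait_{int(rng.integers(0, 50)):02d}",
                neighborhood=GeneNeighborhood(genes=genes),
                target_gene=target,
            )
        )
    return traces


@dataclass
class PrioritizationGroup:
    """Locus-matched candidate variants, exactly one labeled causal."""

    group_id: str
    candidate_ids: list[str]
    causal_id: str

    def __post_init__(self):
        if self.candidate_ids.count(self.causal_id) != 1:
            raise ValueError(f"group {self.group_id}: causal id must appear exactly once")


def gen_prioritization_groups(n_groups: int, group_size: int, seed: int) -> list[PrioritizationGroup]:
    if group_size < 2:
        raise ValueError(f"group_size must be at least 2, got {group_size}")
    if n_groups < 1:
        raise ValueError(f"n_groups must be at least 1, got {n_groups}")
    rng = np.random.default_rng(seed)
    groups = []
    for g in range(n_groups):
        chrom = str(rng.choice(CHROMOSOMES))
        locus = int(rng.integers(10_000, 900_000))
        offsets = rng.choice(np.arange(-5_000, 5_000), size=group_size, replace=False)
        ids = []
        for off in offsets:
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            ids.append(f"{chrom}_{max(1, locus + int(off))}_{ref}_{alt}")
        causal = ids[int(rng.integers(0, group_size))]
        groups.append(PrioritizationGroup(group_id=f"grp{g:04d}", candidate_ids=ids, causal_id=causal))
    return groups


def tiny_frozen_decoder(vocab_size: int, dim: int = 48, seed: int = 0,
                        num_layers: int = 2, num_heads: int = 4,
                        max_len: int = 256) -> TinyCausalDecoder:
    """Construct a seed-determined causal decoder and freeze its weights."""
    rng = np.random.default_rng(seed)
    dec = TinyCausalDecoder(rng, vocab_size=vocab_size, dim=dim,
                            num_layers=num_layers, num_heads=num_heads, max_len=max_len)
    dec.freeze()
    return dec
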