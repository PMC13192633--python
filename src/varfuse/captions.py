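"""Variant records, nearest-gene neighborhoods, and structured JSON captions.

The caption for a single-nucleotide variant is a compact JSON object with
five fields in fixed order — chromosome, variant type (coding/noncoding),
most severe consequence, nearest protein-coding genes, and associated cell
types. Variant identifiers follow the underscore convention
``chrom_pos_ref_alt`` with 1-based positions; gene annotations use half-open
0-based intervals (BED convention) and conversions are centralized here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
CAPTION_FIELDS = ("chromosome", "variant_type", "consequence", "nearest_genes", "cell_types")
VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])


class VariantIdError(ValueError):
    """Raised when a chrom_pos_ref_alt identifier cannot be parsed."""


@dataclass
class VariantRecord:
    """One SNV with its annotation context. ``position`` is 1-based."""

    chromosome: str
    position: int
    ref: str
    alt: str
    variant_type: str  # "coding" | "noncoding"
    consequence: str | None
    nearest_genes: list[str] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")
        for allele in (self.ref, self.alt):
            if allele not in VALID_BASES:
                raise ValueError(f"allele must be a single base in ACGT, got {allele!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}_{self.position}_{self.ref}_{self.alt}"


@dataclass
class NeighborGene:
    gene_id: str
    distance: int  # bp gap to the interval, 0 when the variant lies inside
    overlaps: bool

    @property
    def log_distance(self) -> float:
        return math.log1p(self.distance)


@dataclass
class GeneNeighborhood:
    """Up to ``max_genes`` genes sorted by ascending distance from the variant."""

    genes: list[NeighborGene]

    def __post_init__(self):
        dists = [g.distance for g in self.genes]
        if dists != sorted(dists):
            raise ValueError("neighborhood genes must be sorted by ascending distance")
        for g in self.genes:
            if g.overlaps and g.distance != 0:
                raise ValueError(f"{g.gene_id}: overlapping gene must have distance 0")

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def closest(self) -> NeighborGene | None:
        return self.genes[0] if self.genes else None


@dataclass
class TrackScore:
    track_id: str
    cell_type: str
    effect_size: float

    def __post_init__(self):
        if not math.isfinite(self.effect_size):
            raise ValueError(f"effect size must be finite, got {self.effect_size}")


def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    """Parse ``chrom_pos_ref_alt`` into components.

    The chromosome label is normalized by stripping a leading ``chr``; the
    position must be a positive integer; alleles must be single bases.
    """
    if not variant_id:
        raise VariantIdError("empty variant id")
    fields = variant_id.split("_")
    if len(fields) != 4:
        raise VariantIdError(f"expected 4 fields in {variant_id!r}, got {len(fields)}")
    chrom, pos_s, ref, alt = fields
    chrom = chrom.removeprefix("chr").removeprefix("CHR")
    try:
        pos = int(pos_s)
    except ValueError:
        raise VariantIdError(f"position {pos_s!r} is not an integer") from None
    if pos < 1:
        raise VariantIdError(f"position must be positive (1-based), got {pos}")
    for allele in (ref, alt):
        if allele.upper() not in VALID_BASES or len(allele) != 1:
            raise VariantIdError(f"invalid allele {allele!r}: expected one of A,C,G,T")
    return chrom, pos, ref.upper(), alt.upper()


def _interval_distance(pos_1based: int, start: int, end: int) -> int:
    """bp gap between a 1-based position and a half-open 0-based interval."""
    v = pos_1based - 1
    if start <= v < end:
        return 0
    if v < start:
        return start - v
    return v - end + 1


def _iter_annotation(annotation, chromosome: str):
    """Yield (gene_id, start, end) for one chromosome from a genome object,
    a BED DataFrame (chrom/start/end/name), or a BED file path."""
    if hasattr(annotation, "gene_intervals"):
        for gene_id, start, end, _strand in annotation.gene_intervals.get(chromosome, []):
            yield gene_id, start, end
        return
    if isinstance(annotation, (str, Path)):
        annotation = read_bed(annotation)
    sub = annotation[annotation["chrom"].astype(str) == str(chromosome)]
    for row in sub.itertuples(index=False):
        yield str(row.name), int(row.start), int(row.end)


def nearest_genes(variant: VariantRecord, annotation, max_genes: int = 15) -> GeneNeighborhood:
    """Rank genes by minimal distance to the variant; keep the ``max_genes`` closest.

    Ties are broken by ascending interval start, then lexicographic gene id.
    Strand is ignored. An empty chromosome yields an empty neighborhood with
    a warning rather than an error.
    """
    candidates = []
    for gene_id, start, end in _iter_annotation(annotation, variant.chromosome):
        d = _interval_distance(variant.position, start, end)
        candidates.append((d, start, gene_id))
    if not candidates:
        warnings.warn(f"no genes on chromosome {variant.chromosome}; empty neighborhood")
        return GeneNeighborhood(genes=[])
    candidates.sort()
    top = candidates[:max_genes]
    return GeneNeighborhood(
        genes=[NeighborGene(gene_id=g, distance=d, overlaps=(d == 0)) for d, _s, g in top]
    )


def build_match_filter(locator_closest: str | None, labeled_closest: str | None) -> tuple[bool, str]:
    """Keep a variant iff two independent closest-gene calls agree.

    Returns ``(keep, reason)`` with reason codes ``ok``, ``mismatch``, or
    ``missing_id``. Gene ids are compared after whitespace strip and upper-casing.
    """
    if not locator_closest or not labeled_closest:
        return False, "missing_id"
    if locator_closest.strip().upper() == labeled_closest.strip().upper():
        return True, "ok"
    return False, "mismatch"


def top_tracks(scores: list[TrackScore], k: int = 5) -> list[TrackScore]:
    """The k tracks with largest absolute effect size, descending; ties by track id."""
    return sorted(scores, key=lambda s: (-abs(s.effect_size), s.track_id))[:k]


def interleave_ref_alt(ref_bins: np.ndarray, alt_bins: np.ndarray) -> np.ndarray:
    """Interleave B ref and B alt bin vectors into a 2B sequence: out[2i]=ref[i], out[2i+1]=alt[i]."""
    ref_bins = np.asarray(ref_bins)
    alt_bins = np.asarray(alt_bins)
    if ref_bins.shape != alt_bins.shape:
        raise ValueError(f"ref/alt bin shapes differ: {ref_bins.shape} vs {alt_bins.shape}")
    out = np.empty((2 * ref_bins.shape[0],) + ref_bins.shape[1:], dtype=ref_bins.dtype)
    out[0::2] = ref_bins
    out[1::2] = alt_bins
    return out


def deinterleave_ref_alt(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seq = np.asarray(seq)
    if seq.shape[0] % 2:
        raise ValueError("interleaved sequence must have even length")
    return seq[0::2], seq[1::2]


def build_caption(record: VariantRecord) -> str:
    """Serialize the five caption fields as compact JSON in fixed field order."""
    if record.consequence is None:
        warnings.warn(f"{record.variant_id}: consequence missing; caption carries null")
    doc = {
        "chromosome": str(record.chromosome),
        "variant_type": record.variant_type,
        "consequence": record.consequence,
        "nearest_genes": list(record.nearest_genes),
        "cell_types": list(record.cell_types),
    }
    return json.dumps(doc, separators=(",", ":"))


def parse_caption(caption: str) -> dict:
    doc = json.loads(caption)
    missing = [f for f in CAPTION_FIELDS if f not in doc]
    if missing:
        raise ValueError(f"caption missing fields: {missing}")
    return doc


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def write_bed(df_or_intervals, path) -> None:
    """Write (chrom, start, end, name[, score, strand]) rows as BED."""
    if isinstance(df_or_intervals, pd.DataFrame):
        df = df_or_intervals
    else:
        df = pd.DataFrame(df_or_intervals, columns=["chrom", "start", "end", "name", "score", "strand"])
    df.to_csv(path, sep="\t", header=False, index=False)
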