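"""Evaluation surfaces: per-field caption accuracy, target-gene identification
with a closest-gene baseline and a non-closest stratum, and grouped causal
variant prioritization (Top-k accuracy, mean rank, rank spread).

Rank statistics use the population standard deviation; for a causal variant
placed uniformly at random in a group of n candidates the closed forms are
Top-k = k/n, mean rank (n+1)/2, and stdev sqrt((n^2 - 1) / 12).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .captions import CAPTION_FIELDS
from .synthetic import PrioritizationGroup, TargetGeneTrace
from .tokenizer import split_text

REPORT_FIELDS = ("chromosome", "variant_type", "consequence", "nearest_genes", "cell_types")


@dataclass
class FieldReport:
    accuracies: dict[str, float]
    n: int

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("report requires n > 0")
        for k, v in self.accuracies.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"accuracy for {k} out of [0,1]: {v}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"field": k, "accuracy": v, "n": self.n} for k, v in self.accuracies.items()]
        )


def rouge_l_f1(prediction: str, reference: str) -> float:
    """ROUGE-L F1 over word tokens (longest common subsequence)."""
    p = split_text(prediction.lower())
    r = split_text(reference.lower())
    if not p or not r:
        return 1.0 if p == r else 0.0
    dp = np.zeros((len(p) + 1, len(r) + 1), dtype=np.int64)
    for i, pt in enumerate(p):
        for j, rt in enumerate(r):
            dp[i + 1, j + 1] = dp[i, j] + 1 if pt == rt else max(dp[i, j + 1], dp[i + 1, j])
    lcs = int(dp[-1, -1])
    if lcs == 0:
        return 0.0
    prec, rec = lcs / len(p), lcs / len(r)
    return 2 * prec * rec / (prec + rec)


def _norm(x) -> str:
    return str(x).strip().lower()


def per_field_accuracy(predicted: list[str], gold: list[str],
                       strict_gene_match: bool = False) -> FieldReport:
    """Score predicted caption JSON strings against gold captions.

    Chromosome, variant type, and consequence use normalized exact match;
    nearest genes score a hit when the predicted and gold gene sets intersect
    (exact set equality under ``strict_gene_match``); cell types score mean
    ROUGE-L F1 of the joined lists. An unparseable prediction scores 0 on all
    fields but still counts in n.
    """
    if len(predicted) != len(gold):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(gold)} gold")
    if not gold:
        raise ValueError("empty evaluation set")
    totals = {f: 0.0 for f in REPORT_FIELDS}
    for pred_s, gold_s in zip(predicted, gold):
        gold_doc = json.loads(gold_s)
        try:
            pred_doc = json.loads(pred_s)
            if not isinstance(pred_doc, dict):
                raise ValueError
        except (ValueError, TypeError):
            continue  # scores 0 everywhere for this item
        for f in ("chromosome", "variant_type", "consequence"):
            if _norm(pred_doc.get(f)) == _norm(gold_doc.get(f)):
                totals[f] += 1.0
        pg = {_norm(g) for g in pred_doc.get("nearest_genes") or []}
        gg = {_norm(g) for g in gold_doc.get("nearest_genes") or []}
        if strict_gene_match:
            totals["nearest_genes"] += float(bool(gg) and pg == gg)
        else:
            totals["nearest_genes"] += float(bool(pg & gg))
        pred_ct = " ".join(map(str, pred_doc.get("cell_types") or []))
        gold_ct = " ".join(map(str, gold_doc.get("cell_types") or []))
        totals["cell_types"] += rouge_l_f1(pred_ct, gold_ct)
    n = len(gold)
    return FieldReport(accuracies={f: totals[f] / n for f in REPORT_FIELDS}, n=n)


# -- target-gene identification -------------------------------------------------


def closest_gene_baseline(trace: TargetGeneTrace) -> str | None:
    """Predict the gene at minimal distance to the variant (None if no genes)."""
    return trace.closest_gene


def baseline_accuracy(traces: list[TargetGeneTrace]) -> float:
    if not traces:
        raise ValueError("no traces")
    hits = sum(closest_gene_baseline(t) == t.target_gene for t in traces)
    return hits / len(traces)


def stratify_non_closest(traces: list[TargetGeneTrace]
                         ) -> tuple[list[TargetGeneTrace], list[TargetGeneTrace]]:
    """Return (all traces, subset where the target is not the closest gene)."""
    non_closest = [t for t in traces if t.target_gene != t.closest_gene]
    return list(traces), non_closest


# -- grouped prioritization ------------------------------------------------------


@dataclass
class PrioritizationResult:
    ranks: list[int]
    top_k: dict[int, float]
    mean_rank: float
    std_rank: float  # population standard deviation
    group_sizes: list[int] = field(default_factory=list)

    def __post_init__(self):
        for k in sorted(self.top_k):
            if k > 1 and self.top_k[k] < self.top_k[k - 1] - 1e-12:
                raise ValueError("Top-k must be nondecreasing in k")


def score_prioritization(groups: list[PrioritizationGroup],
                         rankings: dict[str, list[str]],
                         ks: tuple[int, ...] = (1, 2, 3)) -> PrioritizationResult:
    """Rank-based scoring of per-group candidate orderings.

    ``rankings[group_id]`` is the ranked candidate list for that group (most
    to least likely causal). Candidates missing from a ranking are appended in
    the group's input order; a ranking naming an unknown candidate is rejected.
    """
    ranks: list[int] = []
    sizes: list[int] = []
    for grp in groups:
        ranking = list(rankings.get(grp.group_id, []))
        unknown = [c for c in ranking if c not in grp.candidate_ids]
        if unknown:
            raise ValueError(f"group {grp.group_id}: unknown candidates {unknown}")
        seen = set(ranking)
        ranking += [c for c in grp.candidate_ids if c not in seen]
        ranks.append(ranking.index(grp.causal_id) + 1)
        sizes.append(len(grp.candidate_ids))
    arr = np.asarray(ranks, dtype=float)
    return PrioritizationResult(
        ranks=ranks,
        top_k={k: float((arr <= k).mean()) for k in ks},
        mean_rank=float(arr.mean()),
        std_rank=float(arr.std(ddof=0)),
        group_sizes=sizes,
    )


def random_ranking_reference(group_size: int, ks: tuple[int, ...] = (1, 2, 3)
                             ) -> PrioritizationResult:
    """Closed-form scores when the causal variant is ranked uniformly at random.

    Top-k = k/n, mean rank = (n+1)/2, population stdev = sqrt((n^2-1)/12).
    """
    n = group_size
    if n < 1:
        raise ValueError(f"group size must be at least 1, got {n}")
    return PrioritizationResult(
        ranks=list(range(1, n + 1)),
        top_k={k: min(k, n) / n for k in ks},
        mean_rank=(n + 1) / 2.0,
        std_rank=math.sqrt((n * n - 1) / 12.0),
        group_sizes=[n],
    )


def extract_ranking_from_text(text: str, candidate_ids: list[str]) -> list[str]:
    """Ranked list = candidates in first-occurrence order in generated text;
    unmentioned candidates follow in input order."""
    positions = {c: text.find(c) for c in candidate_ids}
    mentioned = sorted((c for c in candidate_ids if positions[c] >= 0),
                       key=lambda c: positions[c])
    return mentioned + [c for c in candidate_ids if positions[c] < 0]


def report_to_tsv(result: PrioritizationResult, path) -> None:
    rows = [{"metric": f"top_{k}", "value": v} for k, v in sorted(result.top_k.items())]
    rows += [{"metric": "mean_rank", "value": result.mean_rank},
             {"metric": "std_rank", "value": result.std_rank}]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


__all__ = [
    "FieldReport", "PrioritizationResult", "per_field_accuracy", "rouge_l_f1",
    "closest_gene_baseline", "baseline_accuracy", "stratify_non_closest",
    "score_prioritization", "random_ranking_reference",
    "extract_ranking_from_text", "report_to_tsv", "CAPTION_FIELDS",
]
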