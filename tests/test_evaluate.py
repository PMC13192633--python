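"""Evaluation harness: per-field scoring, closest-gene baseline and
stratification, and rank-based prioritization metrics against closed forms."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varfuse.evaluate import (
    baseline_accuracy,
    closest_gene_baseline,
    extract_ranking_from_text,
    per_field_accuracy,
    random_ranking_reference,
    rouge_l_f1,
    score_prioritization,
    stratify_non_closest,
)
from varfuse.synthetic import (
    PrioritizationGroup,
    gen_prioritization_groups,
    gen_target_gene_traces,
)


def caption(chrom="1", vtype="noncoding", cons="intron_variant",
            genes=("G1",), cells=("CT1",)):
    return json.dumps({
        "chromosome": chrom, "variant_type": vtype, "consequence": cons,
        "nearest_genes": list(genes), "cell_types": list(cells),
    }, separators=(",", ":"))


class TestPerFieldAccuracy:
    def test_identical_predictions_score_one_everywhere(self):
        gold = [caption(chrom=str(i)) for i in range(5)]
        rep = per_field_accuracy(gold, gold)
        assert all(v == 1.0 for v in rep.accuracies.values())
        assert rep.n == 5

    def test_empty_predictions_score_zero_everywhere(self):
        gold = [caption(), caption(chrom="2")]
        rep = per_field_accuracy(["", "not json"], gold)
        assert all(v == 0.0 for v in rep.accuracies.values())
        assert rep.n == 2

    def test_hand_counted_chromosome_accuracy(self):
        gold = [caption(chrom=str(i)) for i in range(10)]
        pred = [caption(chrom=str(i if i < 7 else 99)) for i in range(10)]
        rep = per_field_accuracy(pred, gold)
        assert rep.accuracies["chromosome"] == pytest.approx(0.7)

    def test_gene_hit_is_set_intersection_unless_strict(self):
        gold = [caption(genes=["G1", "G2"])]
        pred = [caption(genes=["G2", "G9"])]
        assert per_field_accuracy(pred, gold).accuracies["nearest_genes"] == 1.0
        strict = per_field_accuracy(pred, gold, strict_gene_match=True)
        assert strict.accuracies["nearest_genes"] == 0.0

    def test_unparseable_item_counts_in_n(self):
        gold = [caption(), caption()]
        rep = per_field_accuracy([caption(), "{{{"], gold)
        assert rep.n == 2
        assert rep.accuracies["chromosome"] == pytest.approx(0.5)


class TestRougeL:
    def test_exact_match_is_one(self):
        assert rouge_l_f1("CT1 CT2", "CT1 CT2") == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert rouge_l_f1("CT1", "CT9") == 0.0

    def test_hand_computed_subsequence(self):
        # prediction "a b c", reference "a c d": LCS = 2 -> P=2/3, R=2/3, F1=2/3
        assert rouge_l_f1("a b c", "a c d") == pytest.approx(2 / 3)

    def test_both_empty_is_one(self):
        assert rouge_l_f1("", "") == 1.0


class TestClosestGeneBaseline:
    def test_correct_when_target_is_closest(self):
        traces = gen_target_gene_traces(10, 0.0, seed=1)
        assert baseline_accuracy(traces) == 1.0

    def test_exactly_zero_on_non_closest_stratum(self):
        traces = gen_target_gene_traces(50, 1.0, seed=2)
        assert baseline_accuracy(traces) == 0.0

    def test_mixture_accuracy_matches_construction(self):
        traces = gen_target_gene_traces(100, 0.4, seed=3)
        assert baseline_accuracy(traces) == pytest.approx(0.60)

    def test_prediction_is_minimal_distance_gene(self):
        trace = gen_target_gene_traces(1, 0.0, seed=4)[0]
        dists = {g.gene_id: g.distance for g in trace.neighborhood.genes}
        assert dists[closest_gene_baseline(trace)] == min(dists.values())


class TestStratify:
    def test_partition_is_exhaustive_and_disjoint(self):
        traces = gen_target_gene_traces(40, 0.3, seed=5)
        everything, non_closest = stratify_non_closest(traces)
        closest = [t for t in everything if t not in non_closest]
        assert len(closest) + len(non_closest) == len(traces) == 40
        assert len(non_closest) == 12

    def test_extremes(self):
        assert len(stratify_non_closest(gen_target_gene_traces(8, 1.0, seed=6))[1]) == 8
        assert len(stratify_non_closest(gen_target_gene_traces(8, 0.0, seed=6))[1]) == 0


def group_with_rank(gid, size, rank):
    """A group plus a ranking placing the causal candidate at ``rank``."""
    cands = [f"v{gid}_{i}" for i in range(size)]
    causal = cands[0]
    ranking = [c for c in cands if c != causal]
    ranking.insert(rank - 1, causal)
    return PrioritizationGroup(group_id=str(gid), candidate_ids=cands,
                               causal_id=causal), ranking


class TestScorePrioritization:
    def test_perfect_rankings(self):
        groups, rankings = [], {}
        for gid in range(4):
            g, r = group_with_rank(gid, 10, 1)
            groups.append(g)
            rankings[g.group_id] = r
        res = score_prioritization(groups, rankings)
        assert res.top_k == {1: 1.0, 2: 1.0, 3: 1.0}
        assert res.mean_rank == 1.0 and res.std_rank == 0.0

    def test_hand_arithmetic_on_three_groups(self):
        groups, rankings = [], {}
        for gid, rank in enumerate((2, 5, 1)):
            g, r = group_with_rank(gid, 6, rank)
            groups.append(g)
            rankings[g.group_id] = r
        res = score_prioritization(groups, rankings)
        assert res.top_k[1] == pytest.approx(1 / 3)
        assert res.mean_rank == pytest.approx(8 / 3)
        assert res.ranks == [2, 5, 1]

    def test_missing_candidates_appended_in_input_order(self):
        g, _ = group_with_rank(0, 5, 1)
        res = score_prioritization([g], {"0": []})  # empty ranking -> input order
        assert res.ranks == [1]

    def test_unknown_candidate_rejected_naming_group(self):
        g, _ = group_with_rank(7, 3, 1)
        with pytest.raises(ValueError, match="group 7"):
            score_prioritization([g], {"7": ["nonexistent"]})

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_top_k_monotone_and_rank_bounded(self, size, seed):
        rng = np.random.default_rng(seed)
        groups, rankings = [], {}
        for gid in range(5):
            g, _ = group_with_rank(gid, size, 1)
            groups.append(g)
            rankings[g.group_id] = list(rng.permutation(g.candidate_ids))
        res = score_prioritization(groups, rankings)
        assert res.top_k[1] <= res.top_k[2] <= res.top_k[3]
        assert all(1 <= r <= size for r in res.ranks)


class TestRandomRankingReference:
    def test_group_of_ten_closed_forms(self):
        ref = random_ranking_reference(10)
        assert ref.top_k == {1: 0.1, 2: 0.2, 3: 0.3}
        assert ref.mean_rank == 5.5
        assert ref.std_rank == pytest.approx(math.sqrt(99 / 12))

    def test_degenerate_sizes(self):
        one = random_ranking_reference(1)
        assert one.top_k[1] == 1.0 and one.mean_rank == 1.0 and one.std_rank == 0.0
        two = random_ranking_reference(2)
        assert two.top_k[1] == 0.5 and two.mean_rank == 1.5 and two.std_rank == 0.5

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            random_ranking_reference(0)

    def test_exhaustive_enumeration_of_size_four_matches_closed_form(self):
        groups, rankings = [], {}
        for gid, rank in enumerate(range(1, 5)):  # causal at every position once
            g, r = group_with_rank(gid, 4, rank)
            groups.append(g)
            rankings[g.group_id] = r
        enumerated = score_prioritization(groups, rankings)
        ref = random_ranking_reference(4)
        assert enumerated.top_k == ref.top_k
        assert enumerated.mean_rank == ref.mean_rank
        assert enumerated.std_rank == pytest.approx(ref.std_rank)


def test_ranking_extraction_first_occurrence_order():
    cands = ["1_100_A_G", "1_200_C_T", "1_300_G_A"]
    text = "most likely 1_200_C_T then 1_100_A_G"
    assert extract_ranking_from_text(text, cands) == [
        "1_200_C_T", "1_100_A_G", "1_300_G_A"]


def test_prioritization_on_generated_groups_round_trips():
    groups = gen_prioritization_groups(6, 5, seed=8)
    rankings = {g.group_id: sorted(g.candidate_ids) for g in groups}
    res = score_prioritization(groups, rankings)
    assert len(res.ranks) == 6
    assert all(1 <= r <= 5 for r in res.ranks)
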