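"""Caption construction pipeline: variant-ID parsing, nearest-gene ranking,
agreement filtering, track selection, ref/alt interleaving, JSON captions."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varfuse.captions import (
    TrackScore,
    VariantIdError,
    VariantRecord,
    build_caption,
    build_match_filter,
    deinterleave_ref_alt,
    interleave_ref_alt,
    nearest_genes,
    parse_caption,
    parse_variant_id,
    read_bed,
)
from varfuse.synthetic import SyntheticGenome, gen_synthetic_genome


def make_record(chrom="1", pos=100, **kw):
    defaults = dict(chromosome=chrom, position=pos, ref="G", alt="A",
                    variant_type="noncoding", consequence="intron_variant")
    defaults.update(kw)
    return VariantRecord(**defaults)


class TestParseVariantId:
    @pytest.mark.parametrize(
        "vid,expected",
        [
            ("7_117559590_G_A", ("7", 117559590, "G", "A")),
            ("X_1000_C_T", ("X", 1000, "C", "T")),
            ("chr2_500_a_t", ("2", 500, "A", "T")),
        ],
    )
    def test_valid_ids(self, vid, expected):
        assert parse_variant_id(vid) == expected

    @pytest.mark.parametrize(
        "vid,fragment",
        [
            ("7_117559590_G", "4 fields"),
            ("7_xx_G_A", "not an integer"),
            ("7_0_G_A", "positive"),
            ("7_100_G_AA", "allele"),
            ("7_100_N_A", "allele"),
        ],
    )
    def test_malformed_ids_raise_distinct_errors(self, vid, fragment):
        with pytest.raises(VariantIdError, match=fragment):
            parse_variant_id(vid)


class TestNearestGenes:
    def genome(self):
        return SyntheticGenome(
            chrom_lengths={"1": 100_000},
            gene_intervals={"1": [
                ("A", 100, 200, "+"), ("B", 300, 400, "-"), ("C", 150, 180, "+"),
            ]},
        )

    def test_variant_inside_gene_overlaps_with_zero_log_distance(self):
        nb = nearest_genes(make_record(pos=160), self.genome())
        assert nb.genes[0].gene_id in {"A", "C"}
        assert nb.genes[0].overlaps and nb.genes[0].distance == 0
        assert nb.genes[0].log_distance == 0.0

    def test_matches_brute_force_sort_and_caps_at_max(self):
        rng = np.random.default_rng(11)
        genome = gen_synthetic_genome(rng, n_chroms=1, genes_per_chrom=20)
        rec = make_record(chrom="1", pos=int(rng.integers(1, 900_000)))
        nb = nearest_genes(rec, genome, max_genes=15)
        assert len(nb) == 15

        def dist(start, end):
            v = rec.position - 1
            if start <= v < end:
                return 0
            return start - v if v < start else v - end + 1

        brute = sorted(
            (dist(s, e), s, gid) for gid, s, e, _ in genome.gene_intervals["1"]
        )[:15]
        assert nb.gene_ids() == [g for _, _, g in brute]

    def test_small_annotation_returns_all_without_padding(self):
        nb = nearest_genes(make_record(pos=50), self.genome(), max_genes=15)
        assert len(nb) == 3

    def test_empty_chromosome_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no genes"):
            nb = nearest_genes(make_record(chrom="9"), self.genome())
        assert len(nb) == 0

    def test_bed_round_trip_gives_same_neighborhood(self, tmp_path):
        genome = gen_synthetic_genome(np.random.default_rng(3), n_chroms=2)
        bed = tmp_path / "genes.bed"
        genome.to_bed(bed)
        rec = make_record(chrom="2", pos=123_456)
        via_genome = nearest_genes(rec, genome).gene_ids()
        via_bed = nearest_genes(rec, read_bed(bed)).gene_ids()
        assert via_genome == via_bed


class TestMatchFilter:
    def test_agreement_and_disagreement(self):
        assert build_match_filter("BRCA1", "BRCA1") == (True, "ok")
        assert build_match_filter("BRCA1", "BRCA2") == (False, "mismatch")
        assert build_match_filter(None, "BRCA1") == (False, "missing_id")

    def test_survival_fraction_on_injected_disagreements(self):
        # 1000 variants, 73 injected mismatches -> survival 92.7% exactly
        rng = np.random.default_rng(5)
        flags = np.zeros(1000, dtype=bool)
        flags[rng.choice(1000, size=73, replace=False)] = True
        kept = sum(
            build_match_filter("G1", "G2" if bad else "G1")[0] for bad in flags
        )
        assert kept / 1000 == pytest.approx(0.927)


class TestTopTracks:
    def test_hand_sortable_example(self):
        scores = [TrackScore(t, "ct", e) for t, e in
                  [("a", 5), ("b", -7), ("c", 1), ("d", -2), ("e", 3), ("f", 0)]]
        assert [t.track_id for t in top5(scores)] == ["b", "a", "e", "d", "c"]

    def test_fewer_tracks_than_k(self):
        scores = [TrackScore(t, "ct", e) for t, e in [("a", 1), ("b", 2), ("c", 3)]]
        assert len(top5(scores)) == 3

    @given(st.lists(st.tuples(st.integers(0, 999), st.floats(-50, 50)), max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_equals_exhaustive_sort_by_absolute_effect(self, raw):
        scores = [TrackScore(f"t{i:03d}", "ct", e) for i, e in raw]
        got = [t.track_id for t in top5(scores)]
        oracle = [t.track_id for t in
                  sorted(scores, key=lambda s: (-abs(s.effect_size), s.track_id))[:5]]
        assert got == oracle


def top5(scores):
    from varfuse.captions import top_tracks

    return top_tracks(scores, k=5)


class TestInterleave:
    def test_interleaving_doubles_bin_count(self):
        ref = np.random.default_rng(0).normal(size=(256, 8))
        alt = np.random.default_rng(1).normal(size=(256, 8))
        out = interleave_ref_alt(ref, alt)
        assert out.shape == (512, 8)
        assert np.array_equal(out[0], ref[0]) and np.array_equal(out[1], alt[0])

    def test_single_bin(self):
        out = interleave_ref_alt(np.array([[1.0]]), np.array([[2.0]]))
        assert np.array_equal(out, [[1.0], [2.0]])

    @given(st.integers(1, 64), st.integers(1, 8))
    @settings(deadline=None, max_examples=25)
    def test_deinterleave_is_inverse(self, b, d):
        rng = np.random.default_rng(b * 100 + d)
        ref, alt = rng.normal(size=(2, b, d))
        r2, a2 = deinterleave_ref_alt(interleave_ref_alt(ref, alt))
        assert np.array_equal(r2, ref) and np.array_equal(a2, alt)

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            interleave_ref_alt(np.ones((3, 2)), np.ones((4, 2)))


class TestBuildCaption:
    def test_round_trip(self):
        rec = make_record(nearest_genes=["G1", "G2"], cell_types=["CT1"])
        doc = parse_caption(build_caption(rec))
        assert doc == {
            "chromosome": "1", "variant_type": "noncoding",
            "consequence": "intron_variant", "nearest_genes": ["G1", "G2"],
            "cell_types": ["CT1"],
        }

    def test_missing_cell_types_yields_empty_list(self):
        doc = parse_caption(build_caption(make_record()))
        assert doc["cell_types"] == []

    def test_missing_consequence_warns_with_null(self):
        rec = make_record(consequence=None)
        with pytest.warns(UserWarning, match="consequence"):
            caption = build_caption(rec)
        assert json.loads(caption)["consequence"] is None

    def test_serialization_deterministic(self):
        rec = make_record(nearest_genes=["G1"], cell_types=["CT1", "CT2"])
        assert build_caption(rec) == build_caption(make_record(
            nearest_genes=["G1"], cell_types=["CT1", "CT2"]))

    def test_field_order_fixed(self):
        keys = list(json.loads(build_caption(make_record())).keys())
        assert keys == ["chromosome", "variant_type", "consequence",
                        "nearest_genes", "cell_types"]
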