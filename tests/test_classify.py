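"""Positional classification, novelty matching, eRNA flags, breakdowns."""

from collections import Counter

import numpy as np
import pytest

from lincpipe.classify import (
    ClassifiedLncRNA,
    class_breakdown,
    classify_all,
    classify_position,
    erna_overlap_fraction,
    match_catalog,
)
from lincpipe.genomic_io import Annotation, GenomicInterval
from lincpipe.synthetic_data import make_annotation, make_transfrags

from conftest import brute_classify, make_tx, random_transcripts


@pytest.fixture
def annotation():
    return Annotation(
        [
            make_tx("cod.1", "chr1", "+", [(10_000, 10_500), (12_000, 13_000)],
                    "protein_coding", gene="COD"),
            make_tx("ps.1", "chr1", "+", [(50_000, 51_000)], "pseudogene", gene="PS"),
        ]
    )


class TestClassifyPosition:
    def test_empty_chromosome_is_intergenic_by_vacuity(self, annotation):
        t = make_tx("t", "chrZ", "+", [(100, 400)])
        assert classify_position(t, annotation) == "lincRNA"

    def test_opposite_strand_overlap_is_antisense(self, annotation):
        t = make_tx("t", "chr1", "-", [(10_200, 10_700)])
        assert classify_position(t, annotation) == "antisense"

    def test_intronic_opposite_strand_antisense_in_span_mode_only(self, annotation):
        t = make_tx("t", "chr1", "-", [(10_800, 11_500)])  # inside the intron
        assert classify_position(t, annotation, "span") == "antisense"
        assert classify_position(t, annotation, "exon") == "lincRNA"

    def test_pseudogene_precedence_over_antisense(self):
        ann = Annotation(
            [
                make_tx("cod.1", "chr1", "+", [(100, 900)], "protein_coding", gene="C"),
                make_tx("ps.1", "chr1", "+", [(600, 1500)], "pseudogene", gene="P"),
            ]
        )
        t = make_tx("t", "chr1", "-", [(500, 1000)])
        assert classify_position(t, ann) == "pseudogene"

    def test_no_overlap_is_lincRNA(self, annotation):
        t = make_tx("t", "chr1", "+", [(20_000, 20_500)])
        assert classify_position(t, annotation) == "lincRNA"

    def test_table1_geometry_nearby_but_disjoint_is_lincRNA(self, annotation):
        """A lincRNA 1,409 bp from a coding TSS with zero overlap stays lincRNA."""
        t = make_tx("t", "chr1", "-", [(7000, 10_000 - 1409)])
        assert classify_position(t, annotation) == "lincRNA"

    def test_oracle_equivalence_on_random_transcripts(self, annotation):
        ann = make_annotation(n_coding=40, n_pseudo=15, chrom_length=3_000_000, seed=7)
        rng = np.random.default_rng(42)
        for t in random_transcripts(rng, 200, 3_000_000):
            for mode in ("span", "exon"):
                assert classify_position(t, ann, mode) == brute_classify(t, ann, mode)

    def test_shift_invariance(self, annotation):
        rng = np.random.default_rng(1)
        ts = random_transcripts(rng, 50, 2_000_000)
        ann = make_annotation(n_coding=20, n_pseudo=8, chrom_length=2_000_000, seed=2)
        shifted_ann = Annotation([t.shifted(10_000) for t in ann.transcripts()])
        for t in ts:
            assert classify_position(t, ann) == classify_position(
                t.shifted(10_000), shifted_ann
            )

    def test_strand_flip_of_both_leaves_classes_unchanged(self):
        def flip(t):
            s = "+" if t.strand == "-" else "-"
            return make_tx(
                t.transcript_id, t.chrom, s,
                [(e.start, e.end) for e in t.exons], t.biotype, t.gene_id
            )

        ann = make_annotation(n_coding=20, n_pseudo=8, chrom_length=2_000_000, seed=5)
        flipped_ann = Annotation([flip(t) for t in ann.transcripts()])
        rng = np.random.default_rng(9)
        for t in random_transcripts(rng, 50, 2_000_000):
            assert classify_position(t, ann) == classify_position(flip(t), flipped_ann)

    def test_generator_truth_recovered_exactly(self):
        ann = make_annotation(n_coding=25, n_pseudo=10, chrom_length=4_000_000, seed=8)
        transfrags, _, truth = make_transfrags(ann, n=60, seed=9)
        for t in transfrags:
            assert classify_position(t, ann) == truth.classes[t.transcript_id]


class TestMatchCatalog:
    def test_identical_exon_chain_is_known(self):
        t = make_tx("t", "chr1", "+", [(100, 400), (600, 900)])
        cat = Annotation([make_tx("c", "chr1", "+", [(100, 400), (600, 900)])])
        status, ids = match_catalog(t, cat)
        assert status == "known" and ids == ["c"]

    def test_ten_percent_overlap_is_novel_at_half(self):
        t = make_tx("t", "chr1", "+", [(0, 1000)])
        cat = Annotation([make_tx("c", "chr1", "+", [(900, 1900)])])  # 100/1000 shared
        assert match_catalog(t, cat, 0.5)[0] == "novel"
        assert match_catalog(t, cat, 0.1)[0] == "known"

    def test_opposite_strand_never_matches(self):
        t = make_tx("t", "chr1", "+", [(100, 400)])
        cat = Annotation([make_tx("c", "chr1", "-", [(100, 400)])])
        assert match_catalog(t, cat)[0] == "novel"

    def test_reciprocality(self):
        # overlap covers all of t but 10% of the huge catalog entry
        t = make_tx("t", "chr1", "+", [(0, 100)])
        cat = Annotation([make_tx("c", "chr1", "+", [(0, 1000)])])
        assert match_catalog(t, cat, 0.5)[0] == "novel"

    def test_threshold_validation(self):
        t = make_tx("t", "chr1", "+", [(0, 100)])
        with pytest.raises(ValueError):
            match_catalog(t, Annotation(), 0.0)
        with pytest.raises(ValueError):
            match_catalog(t, Annotation(), 1.5)


class TestErna:
    def _lncs(self, n=4):
        return [
            ClassifiedLncRNA(make_tx(f"t{i}", "chr1", "+", [(i * 1000, i * 1000 + 300)]),
                             "lincRNA")
            for i in range(1, n + 1)
        ]

    def test_empty_enhancer_list_gives_zero(self):
        frac, flags = erna_overlap_fraction(self._lncs(), [])
        assert frac == 0.0 and not any(flags.values())

    def test_all_inside_gives_one(self):
        lncs = self._lncs()
        frac, _ = erna_overlap_fraction(lncs, [GenomicInterval("chr1", 0, 10_000)])
        assert frac == 1.0 and all(l.erna_overlap for l in lncs)

    def test_strand_blind_single_base(self):
        lncs = self._lncs(1)
        frac, _ = erna_overlap_fraction(lncs, [GenomicInterval("chr1", 1299, 1300, "-")])
        assert frac == 1.0

    def test_empty_lnc_list_rejected(self):
        with pytest.raises(ValueError):
            erna_overlap_fraction([], [])


class TestBreakdown:
    def _labelled(self, counts):
        out = []
        i = 0
        for cls, n in counts.items():
            for _ in range(n):
                out.append(
                    ClassifiedLncRNA(
                        make_tx(f"b{i}", "chr1", "+", [(i * 500, i * 500 + 200)]), cls
                    )
                )
                i += 1
        return out

    def test_printed_125_breakdown(self):
        """93/13/19 of 125 renders as the published 74% / 11% / 15%."""
        b = class_breakdown(self._labelled({"lincRNA": 93, "antisense": 13, "pseudogene": 19}))
        assert b["percent"] == {"lincRNA": 74, "antisense": 11, "pseudogene": 15}
        assert sum(b["percent"].values()) == 100
        assert b["percent_raw"]["lincRNA"] == pytest.approx(74.4)

    def test_single_class(self):
        b = class_breakdown(self._labelled({"lincRNA": 1}))
        assert b["percent"]["lincRNA"] == 100 and b["total"] == 1

    def test_counts_match_tally_oracle(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["lincRNA", "antisense", "pseudogene"], size=200)
        lncs = self._labelled(Counter(labels))
        b = class_breakdown(lncs)
        assert b["counts"] == dict(Counter(labels)) | {
            c: 0 for c in ("lincRNA", "antisense", "pseudogene") if c not in labels
        }
        assert sum(b["counts"].values()) == 200

    def test_classify_all_is_total_and_exclusive(self):
        ann = make_annotation(n_coding=15, n_pseudo=8, chrom_length=2_500_000, seed=4)
        transfrags, catalog, _ = make_transfrags(ann, n=40, seed=6)
        classified = classify_all(transfrags, ann, {"cat": catalog})
        assert len(classified) == 40
        b = class_breakdown(classified)
        assert sum(b["counts"].values()) == 40
        # novelty consistent with matched catalog tags
        for c in classified:
            assert (c.novelty == "known") == bool(c.matched_catalogs)
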