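"""Generator contracts: determinism, truth consistency, planted effects."""

import json
from collections import Counter

import numpy as np
import pytest

from lincpipe.classify import classify_position
from lincpipe.diffexp import de_test
from lincpipe.genomic_io import read_expression_table
from lincpipe.synthetic_data import (
    SyntheticTruth,
    _allocate,
    make_annotation,
    make_assays,
    make_enhancers,
    make_expression,
    make_transfrags,
    simulate_all,
)


class TestMakeAnnotation:
    def test_same_seed_is_identical(self):
        a1 = make_annotation(n_coding=10, n_pseudo=4, chrom_length=2_000_000, seed=3)
        a2 = make_annotation(n_coding=10, n_pseudo=4, chrom_length=2_000_000, seed=3)
        assert [
            (t.transcript_id, t.exons, t.biotype) for t in a1.transcripts()
        ] == [(t.transcript_id, t.exons, t.biotype) for t in a2.transcripts()]

    def test_no_coding_genes_leaves_only_pseudogenes(self):
        ann = make_annotation(n_coding=0, n_pseudo=5, chrom_length=1_000_000, seed=1)
        assert {t.biotype for t in ann.transcripts()} == {"pseudogene"}

    def test_gene_spans_never_overlap(self):
        ann = make_annotation(n_coding=40, n_pseudo=15, chrom_length=6_000_000, seed=2)
        spans = sorted((t.start, t.end) for t in ann.transcripts())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_mean_exon_count_near_configured_target(self):
        # coding exons uniform on 4..20 -> expected mean 12
        means = []
        for seed in range(10):
            ann = make_annotation(n_coding=30, n_pseudo=0, chrom_length=6_000_000, seed=seed)
            means.append(np.mean([t.n_exons for t in ann.transcripts()]))
        assert 12 * 0.8 <= float(np.mean(means)) <= 12 * 1.2


class TestAllocation:
    def test_exact_integer_allocation(self):
        assert _allocate(200, (0.65, 0.15, 0.20)) == [130, 30, 40]

    def test_rounding_sums_to_n(self):
        counts = _allocate(101, (1 / 3, 1 / 3, 1 / 3))
        assert sum(counts) == 101

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            _allocate(10, (0.5, 0.6))


@pytest.fixture(scope="module")
def dataset():
    ann = make_annotation(n_coding=45, n_pseudo=15, chrom_length=8_000_000, seed=10)
    transfrags, catalog, truth = make_transfrags(ann, n=120, seed=11)
    return ann, transfrags, catalog, truth


class TestMakeTransfrags:

    def test_pure_lincRNA_mix(self):
        ann = make_annotation(n_coding=10, n_pseudo=3, chrom_length=3_000_000, seed=12)
        tf, _, truth = make_transfrags(ann, n=20, class_mix=(1.0, 0.0, 0.0), seed=13)
        assert all(c == "lincRNA" for c in truth.classes.values())
        for t in tf:
            assert classify_position(t, ann) == "lincRNA"

    def test_truth_geometry_audit(self, dataset):
        ann, transfrags, _, truth = dataset
        genes = list(ann.transcripts())
        for t in transfrags:
            cls = truth.classes[t.transcript_id]
            overlapping = [
                g for g in genes
                if g.chrom == t.chrom and t.start < g.end and g.start < t.end
            ]
            if cls == "lincRNA":
                assert overlapping == []
            elif cls == "antisense":
                assert any(
                    g.biotype == "protein_coding" and g.strand != t.strand
                    for g in overlapping
                )
                assert not any(g.biotype == "pseudogene" for g in overlapping)
            else:
                assert any(g.biotype == "pseudogene" for g in overlapping)

    def test_classification_matches_truth_for_every_transcript(self, dataset):
        ann, transfrags, _, truth = dataset
        assert {
            t.transcript_id: classify_position(t, ann) for t in transfrags
        } == truth.classes

    def test_catalog_fraction_and_novelty(self, dataset):
        _, transfrags, catalog, truth = dataset
        n_known = sum(v == "known" for v in truth.novelty.values())
        assert n_known == round(0.75 * len(transfrags))
        assert catalog.n_transcripts == n_known

    def test_flanking_distances_below_5kb(self, dataset):
        _, _, _, truth = dataset
        assert truth.flanking_pairs
        assert all(d < 5000 for d in truth.flanking_distance_bp.values())

    def test_transfrag_spans_disjoint(self, dataset):
        _, transfrags, _, _ = dataset
        spans = sorted((t.start, t.end) for t in transfrags)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestMakeEnhancers:
    def test_planted_overlap_fraction_is_exact(self):
        ann = make_annotation(n_coding=40, n_pseudo=12, chrom_length=8_000_000, seed=14)
        tf, _, truth = make_transfrags(ann, n=100, seed=15)
        enhancers = make_enhancers(ann, tf, truth, overlap_frac=0.05, seed=16)
        from lincpipe.classify import ClassifiedLncRNA, erna_overlap_fraction

        lncs = [ClassifiedLncRNA(t, truth.classes[t.transcript_id]) for t in tf]
        frac, flags = erna_overlap_fraction(lncs, enhancers)
        assert frac == pytest.approx(0.05)
        assert sorted(tid for tid, f in flags.items() if f) == truth.erna_ids


class TestMakeExpression:
    def test_null_generator_stays_near_type_one_rate(self):
        ann = make_annotation(n_coding=10, n_pseudo=8, chrom_length=3_000_000, seed=17)
        tf, _, truth = make_transfrags(ann, n=60, flanking_frac=0.0, seed=18)
        table = make_expression(ann, tf, truth, de_frac=0.0, seed=19)
        assert not any(truth.de_status[t.transcript_id] for t in tf)
        ps = [
            de_test(
                [v for k, v in table[t.transcript_id].items() if k.startswith("control_")],
                [v for k, v in table[t.transcript_id].items() if k.startswith("IL1b_")],
            )[2]
            for t in tf
        ]
        assert np.mean(np.array(ps) < 0.05) < 0.2  # loose null sanity at n=60

    def test_noiseless_limit_recovers_planted_fold_change_exactly(self):
        ann = make_annotation(n_coding=10, n_pseudo=5, chrom_length=3_000_000, seed=20)
        tf, _, truth = make_transfrags(ann, n=30, flanking_frac=0.0, seed=21)
        table = make_expression(
            ann, tf, truth, de_frac=0.3, lfc_dist=(3.0, 0.0), noise_sd=0.0, seed=22
        )
        planted = [tid for tid in truth.de_status if truth.de_status[tid]
                   and tid.startswith("XLOC")]
        assert planted
        for tid in planted:
            row = table[tid]
            ctrl = [v for k, v in row.items() if k.startswith("control_")]
            stim = [v for k, v in row.items() if k.startswith("IL1b_")]
            lfc, _, _ = de_test(ctrl, stim, pseudocount=0.0)
            assert lfc == pytest.approx(truth.true_log2_fc[tid], abs=1e-9)
            assert abs(lfc) == pytest.approx(3.0, abs=1e-9)

    def test_fpkm_strictly_positive_and_floor_respected(self):
        ann = make_annotation(n_coding=20, n_pseudo=6, chrom_length=4_000_000, seed=23)
        tf, _, truth = make_transfrags(ann, n=40, seed=24)
        table = make_expression(ann, tf, truth, seed=25)
        values = np.array([v for row in table.values() for v in row.values()])
        assert (values > 0).all()


class TestMakeAssays:
    def test_ct_values_in_plausible_range(self):
        ct, _ = make_assays(seed=1)
        assert ct["ct_target"].between(10, 40).all()
        assert ct["ct_reference"].between(5, 40).all()

    def test_zero_planted_knockdown_gives_rq_ratio_one(self):
        ct, _ = make_assays(knockdown={"X": 0.0}, ct_noise_sd=0.0, seed=2)
        from lincpipe.assay_stats import ddct_relative_expression

        out = ddct_relative_expression(ct, "NTC")
        assert out["rq"].to_numpy() == pytest.approx(np.ones(len(out)))

    def test_determinism(self):
        a = make_assays(seed=7)
        b = make_assays(seed=7)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestSimulateAll:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        p1 = simulate_all(tmp_path / "a", seed=5, n_transfrags=60, n_coding=30, n_pseudo=10)
        p2 = simulate_all(tmp_path / "b", seed=5, n_transfrags=60, n_coding=30, n_pseudo=10)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_truth_round_trips_losslessly(self, synth_dataset):
        truth = SyntheticTruth.from_json(synth_dataset["truth"])
        tmp = synth_dataset["truth"].parent / "truth_rt.json"
        truth.to_json(tmp)
        assert json.loads(tmp.read_text()) == json.loads(synth_dataset["truth"].read_text())

    def test_emitted_formats_are_readable(self, synth_dataset):
        table = read_expression_table(synth_dataset["expression"])
        truth = SyntheticTruth.from_json(synth_dataset["truth"])
        assert set(truth.classes) <= set(table)
        counts = Counter(truth.classes.values())
        assert sum(counts.values()) == 200
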