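"""Ground-truth guarantees of the synthetic bundle generator."""

import numpy as np
import pytest

from lincatlas.algebra import transcript_length
from lincatlas.filters import MotifMatcher, six_frame_translate
from lincatlas.model import PipelineConfig
from lincatlas.novelty import NoveltyLabel, classify_catalog, classify_transcript
from lincatlas.simulate import (
    DOMAIN_MOTIF,
    SimulationError,
    SimulationParams,
    generate_bundle,
    generate_reference,
    plant_novel_lincs,
    simulate_method_catalogs,
    write_bundle,
)

SMALL = dict(n_planted=15, n_coding=30, n_known_linc=5, n_chroms=2)


class TestGenerateReference:
    def test_gene_counts_and_biotypes(self):
        params = SimulationParams(seed=5, **SMALL)
        reference = generate_reference(params)
        assert reference.n_genes == 35
        coding = [
            l for l in reference.loci
            if any(
                t.attributes.get("gene_biotype") == "protein_coding"
                for t in l.transcripts
            )
        ]
        assert len(coding) == 30

    def test_reference_loci_do_not_overlap(self):
        params = SimulationParams(seed=5, **SMALL)
        reference = generate_reference(params)
        by_chrom = {}
        for locus in reference.loci:
            by_chrom.setdefault(locus.chrom, []).append(locus.span)
        for spans in by_chrom.values():
            spans.sort(key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start

    def test_same_seed_is_deterministic(self):
        params = SimulationParams(seed=11, **SMALL)
        assert generate_reference(params) == generate_reference(params)

    def test_genome_too_small_raises(self):
        with pytest.raises(SimulationError, match="too small"):
            generate_reference(
                SimulationParams(seed=0, n_chroms=1, chrom_length=50_000,
                                 n_coding=30, n_planted=5)
            )


class TestPlantNovelLincs:
    def test_planted_are_intergenic_multi_exonic_and_long(self):
        params = SimulationParams(seed=7, **SMALL)
        reference = generate_reference(params)
        planted, truth = plant_novel_lincs(reference, params)
        assert len(planted) == 15 and len(truth) == 15
        for t in planted:
            assert t.n_exons >= 2
            assert transcript_length(t) > 200
            cls = classify_transcript(t, reference, PipelineConfig())
            assert cls.label is NoveltyLabel.INTERGENIC_NOVEL

    def test_zero_planted_gives_empty_truth(self):
        params = SimulationParams(seed=7, n_planted=0, n_coding=10,
                                  n_known_linc=2, n_chroms=1)
        planted, truth = plant_novel_lincs(generate_reference(params), params)
        assert planted == [] and len(truth) == 0


class TestSimulateMethodCatalogs:
    def test_detection_probability_one_puts_every_linc_in_every_method(self):
        params = SimulationParams(seed=3, p_detect=(1.0, 1.0, 1.0), **SMALL)
        reference = generate_reference(params)
        planted, _ = plant_novel_lincs(reference, params)
        catalogs, detected = simulate_method_catalogs(reference, planted, params)
        assert detected.all()
        for mc, label in zip(catalogs, params.method_labels):
            ids = {t.transcript_id for t in mc.catalog.transcripts()}
            for t in planted:
                assert f"{label}|{t.transcript_id}" in ids

    def test_detection_probability_zero_leaves_only_artifacts(self):
        params = SimulationParams(seed=3, p_detect=(0.0, 0.0, 0.0), **SMALL)
        reference = generate_reference(params)
        planted, _ = plant_novel_lincs(reference, params)
        catalogs, detected = simulate_method_catalogs(reference, planted, params)
        assert not detected.any()
        for mc in catalogs:
            for t in mc.catalog.transcripts():
                assert "|PL" not in t.transcript_id

    def test_jitter_preserves_intron_chains(self):
        params = SimulationParams(seed=9, p_detect=(1.0, 1.0, 1.0),
                                  end_jitter=30, **SMALL)
        reference = generate_reference(params)
        planted, _ = plant_novel_lincs(reference, params)
        catalogs, _ = simulate_method_catalogs(reference, planted, params)
        by_base = {t.transcript_id: t for t in planted}
        for mc in catalogs:
            for t in mc.catalog.transcripts():
                base_id = t.transcript_id.split("|", 1)[-1]
                if base_id in by_base:
                    base = by_base[base_id]
                    assert [
                        (e.start, e.end) for e in t.exons[1:-1]
                    ] == [(e.start, e.end) for e in base.exons[1:-1]]
                    assert t.exons[0].end == base.exons[0].end
                    assert t.exons[-1].start == base.exons[-1].start

    def test_artifact_classes_each_target_one_filter(self):
        params = SimulationParams(seed=13, p_detect=(0.0, 0.0, 0.0), **SMALL)
        bundle = generate_bundle(params)
        reference = bundle.reference
        config = PipelineConfig()
        for mc in bundle.method_catalogs:
            classes = classify_catalog(mc.catalog, reference, config)
            for t in mc.catalog.transcripts():
                tid = t.transcript_id
                label = classes[tid].label
                if "|KRE" in tid:
                    assert label is NoveltyLabel.KNOWN
                elif "|ISO" in tid:
                    assert label is NoveltyLabel.NOVEL_ISOFORM
                elif "|MONO" in tid:
                    assert t.n_exons == 1  # dies at the structural filter
                elif "|SHORT" in tid:
                    assert t.n_exons >= 2 and transcript_length(t) <= 200
                elif "|CC" in tid:
                    assert label is NoveltyLabel.INTERGENIC_NOVEL
                    score = bundle.scores[tid]
                    assert score > 100.0  # dies at the coding filter


class TestScoresSequencesExpression:
    def test_planted_scores_below_cutoff_and_sequences_motif_free(self):
        params = SimulationParams(seed=21, **SMALL)
        bundle = generate_bundle(params)
        matcher = MotifMatcher([DOMAIN_MOTIF])
        for tid, score in bundle.scores.scores.items():
            if "|PL" in tid:
                assert score <= 100.0
                frames = six_frame_translate(bundle.sequences[tid])
                assert not any(matcher(p) for p in frames)

    def test_every_second_contaminant_carries_the_motif(self):
        params = SimulationParams(seed=21, coding_contaminant_rate=0.3, **SMALL)
        bundle = generate_bundle(params)
        matcher = MotifMatcher([DOMAIN_MOTIF])
        with_motif = {
            tid for tid, seq in bundle.sequences.items()
            if "|CC" in tid and any(matcher(p) for p in six_frame_translate(seq))
        }
        assert with_motif  # at least contaminant 0 in each method
        for tid in with_motif:
            assert int(tid.split("|CC")[1]) % 2 == 0

    def test_below_floor_fraction_is_deterministic_count(self):
        params = SimulationParams(seed=4, fraction_below_floor=0.4, **SMALL)
        bundle = generate_bundle(params)
        below = bundle.truth["below_floor"]
        assert below.sum() == round(0.4 * 15) == 6
        for _, row in bundle.truth.iterrows():
            if row.below_floor:
                assert bundle.expression.max_fpkm(row.expected_name) < 0.21
            else:
                assert bundle.expression.max_fpkm(row.expected_name) >= 0.21

    def test_same_seed_gives_byte_identical_bundle_files(self, tmp_path):
        params = SimulationParams(seed=17, **SMALL)
        p1 = write_bundle(generate_bundle(params), tmp_path / "a")
        p2 = write_bundle(generate_bundle(params), tmp_path / "b")
        for key in ("reference", "method_1", "method_2", "method_3",
                    "fasta", "scores", "fpkm", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_expected_survival_recomputable_from_truth_columns(self):
        params = SimulationParams(seed=29, fraction_below_floor=0.2, **SMALL)
        truth = generate_bundle(params).truth
        recomputed = (truth["n_methods_detected"] >= 2) & ~truth["below_floor"]
        assert (truth["expected_survival"] == recomputed).all()
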