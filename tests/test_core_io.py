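"""GTF / TSV / FASTA round trips, coordinate conventions, and validation."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from lincatlas.io import (
    read_coding_scores,
    read_expression_table,
    read_gtf,
    write_expression_table,
    write_gtf,
)
from lincatlas.model import (
    ExpressionMatrix,
    GenomeInterval,
    GtfParseError,
    ModelValidationError,
    TranscriptModel,
)

from conftest import catalog_of, random_transcript, tx


def gtf_line(chrom, start1, end1, strand, gene, tid, feature="exon"):
    attrs = f'gene_id "{gene}"; transcript_id "{tid}";'
    return f"{chrom}\tsrc\t{feature}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}"


class TestReadGtf:
    def test_one_based_inclusive_becomes_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line("chr1", 101, 200, "+", "g1", "t1") + "\n")
        catalog = read_gtf(p)
        (exon,) = next(catalog.transcripts()).exons
        assert (exon.start, exon.end) == (100, 200)
        assert exon.length == 100

    def test_exons_grouped_and_sorted_by_transcript(self, tmp_path):
        p = tmp_path / "a.gtf"
        lines = [
            gtf_line("chr1", 301, 400, "+", "g1", "TCONS_1"),
            gtf_line("chr1", 101, 200, "+", "g1", "TCONS_1"),
        ]
        p.write_text("\n".join(lines) + "\n")
        catalog = read_gtf(p)
        (t,) = list(catalog.transcripts())
        assert t.transcript_id == "TCONS_1"
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]

    def test_empty_file_gives_empty_catalog(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert read_gtf(p).n_genes == 0

    def test_non_exon_features_are_ignored(self, tmp_path):
        p = tmp_path / "a.gtf"
        lines = [
            gtf_line("chr1", 1, 500, "+", "g1", "t1", feature="transcript"),
            gtf_line("chr1", 101, 200, "+", "g1", "t1"),
        ]
        p.write_text("\n".join(lines) + "\n")
        assert next(read_gtf(p).transcripts()).n_exons == 1

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\tsrc\texon\t101\t200\t.\t+\t.",  # 8 columns
            gtf_line("chr1", 200, 100, "+", "g", "t"),  # end < start
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g";',  # no transcript_id
            "chr1\tsrc\texon\tx\t200\t.\t+\t.\t" + 'gene_id "g"; transcript_id "t";',
        ],
    )
    def test_malformed_line_raises_with_line_number(self, tmp_path, line):
        p = tmp_path / "bad.gtf"
        p.write_text(line + "\n")
        with pytest.raises(GtfParseError, match=":1"):
            read_gtf(p)

    def test_mixed_chrom_transcript_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        lines = [
            gtf_line("chr1", 101, 200, "+", "g", "tmix"),
            gtf_line("chr2", 301, 400, "+", "g", "tmix"),
        ]
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ModelValidationError, match="tmix"):
            read_gtf(p)

    def test_shuffling_lines_gives_identical_catalog(self, tmp_path, rng):
        transcripts = [random_transcript(rng, f"t{i}") for i in range(15)]
        lines = []
        for t in transcripts:
            for e in t.exons:
                lines.append(
                    gtf_line(t.chrom, e.start + 1, e.end, t.strand, t.gene_id,
                             t.transcript_id)
                )
        a, b = tmp_path / "a.gtf", tmp_path / "b.gtf"
        a.write_text("\n".join(lines) + "\n")
        rng.shuffle(lines)
        b.write_text("\n".join(lines) + "\n")
        assert read_gtf(a) == read_gtf(b)


@st.composite
def catalogs(draw):
    seed = draw(st.integers(0, 10_000))
    r = random.Random(seed)
    n = draw(st.integers(0, 12))
    txs = [random_transcript(r, f"t{i}") for i in range(n)]
    prov = {
        t.transcript_id: frozenset(r.sample(["a", "b", "c"], r.randint(1, 2)))
        for t in txs
        if r.random() < 0.5
    }
    return catalog_of(*txs, provenance=prov)


class TestWriteGtf:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(catalogs())
    def test_round_trip_is_identity(self, tmp_path_factory, catalog):
        p = tmp_path_factory.mktemp("rt") / "c.gtf"
        write_gtf(catalog, p)
        assert read_gtf(p) == catalog

    def test_inverse_coordinate_conversion(self, tmp_path):
        p = tmp_path / "c.gtf"
        write_gtf(catalog_of(tx("t1", [(100, 200)])), p)
        cols = p.read_text().strip().split("\t")
        assert (cols[3], cols[4]) == ("101", "200")

    def test_output_sorted_chrom_major(self, tmp_path):
        catalog = catalog_of(
            tx("tB", [(50, 150)], chrom="chr2"),
            tx("tA", [(500, 600)], chrom="chr1"),
        )
        p = tmp_path / "c.gtf"
        write_gtf(catalog, p)
        chroms = [l.split("\t")[0] for l in p.read_text().splitlines()]
        assert chroms == sorted(chroms)


class TestScoreTable:
    def test_reads_negative_scores(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("transcript_id\tscore\nTCONS_1\t-25.3\n")
        assert read_coding_scores(p)["TCONS_1"] == pytest.approx(-25.3)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("transcript_id\tscore\nt\t1\nt\t2\n")
        with pytest.raises(ModelValidationError):
            read_coding_scores(p)

    def test_non_numeric_score_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("transcript_id\tscore\nt\thigh\n")
        with pytest.raises(GtfParseError):
            read_coding_scores(p)

    def test_empty_table(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("")
        assert len(read_coding_scores(p)) == 0


class TestExpressionTable:
    def test_shape_and_round_trip(self, tmp_path):
        import numpy as np

        matrix = ExpressionMatrix(
            genes=("g1", "g2"),
            populations=tuple(f"p{i}" for i in range(13)),
            values=np.arange(26, dtype=float).reshape(2, 13),
        )
        p = tmp_path / "fpkm.tsv"
        write_expression_table(matrix, p)
        back = read_expression_table(p)
        assert back.genes == matrix.genes
        assert back.populations == matrix.populations
        assert (back.values == matrix.values).all()

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "fpkm.tsv"
        p.write_text("gene_id\tp1\tp2\ng1\t0.5\t-1.0\n")
        with pytest.raises(ModelValidationError):
            read_expression_table(p)

    def test_missing_cell_rejected(self, tmp_path):
        p = tmp_path / "fpkm.tsv"
        p.write_text("gene_id\tp1\tp2\ng1\t0.5\t\n")
        with pytest.raises(GtfParseError):
            read_expression_table(p)


class TestModelInvariants:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ModelValidationError, match="overlapping"):
            tx("t", [(0, 100), (50, 150)])

    def test_exons_sorted_on_construction(self):
        t = TranscriptModel(
            transcript_id="t",
            gene_id="g",
            exons=(
                GenomeInterval("chr1", 300, 400, "+"),
                GenomeInterval("chr1", 0, 100, "+"),
            ),
        )
        assert t.start == 0 and t.end == 400

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ModelValidationError):
            GenomeInterval("chr1", 100, 100, "+")
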