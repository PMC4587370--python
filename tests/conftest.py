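import random

import pytest

from lincatlas.model import (
    GeneLocus,
    GenomeInterval,
    TranscriptCatalog,
    TranscriptModel,
)


def tx(tid, exons, chrom="chr1", strand="+", gene=None, attrs=None):
    """Shorthand transcript builder: exons as (start, end) pairs."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or f"G_{tid}",
        exons=tuple(GenomeInterval(chrom, s, e, strand) for s, e in exons),
        attributes=attrs or {},
    )


def catalog_of(*transcripts, provenance=None):
    """One locus per gene_id, no clustering."""
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    loci = tuple(
        GeneLocus(gene_id=g, transcripts=tuple(ts)) for g, ts in by_gene.items()
    )
    return TranscriptCatalog(loci=loci, provenance=provenance or {})


def random_transcript(rng: random.Random, tid: str, chrom=None, strand=None,
                      span=4_000):
    """A small random multi- or mono-exonic transcript for oracle tests."""
    chrom = chrom or rng.choice(["chr1", "chr2"])
    strand = strand or rng.choice(["+", "-"])
    n_exons = rng.randint(1, 4)
    pos = rng.randrange(0, span)
    exons = []
    for _ in range(n_exons):
        length = rng.randint(20, 150)
        exons.append((pos, pos + length))
        pos += length + rng.randint(10, 200)
    return tx(tid, exons, chrom=chrom, strand=strand)


@pytest.fixture
def rng():
    return random.Random(20_240_917)
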