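"""Interval and transcript-model arithmetic.

The primitives here — mature length, intron chains, exonic overlap, and
single-linkage locus clustering — are the substrate for every downstream
stage: novelty classification, consensus merging, and gene-level filtering.

Two transcripts are treated as the same isoform when their intron chains are
identical (same chromosome, strand, and ordered intron intervals); end
coordinates are deliberately ignored because assembler end positions are
unreliable. A gene locus is a connected component of transcripts under
exonic overlap (>= 1 shared base), optionally restricted to a single strand.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import GeneLocus, GenomeInterval, TranscriptModel

ChainKey = tuple[str, str, tuple[tuple[int, int], ...]]


def transcript_length(t: TranscriptModel) -> int:
    """Mature transcript length: the sum of exon lengths, not the span."""
    return sum(e.length for e in t.exons)


def intron_chain(t: TranscriptModel) -> tuple[GenomeInterval, ...]:
    """The ordered gaps between consecutive exons; empty for mono-exonic."""
    return tuple(
        GenomeInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    )


def chain_key(t: TranscriptModel) -> ChainKey | None:
    """Hashable intron-chain identity, or None for mono-exonic transcripts."""
    if t.n_exons < 2:
        return None
    return (t.chrom, t.strand, tuple((i.start, i.end) for i in intron_chain(t)))


def same_intron_chain(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff both are multi-exonic with identical intron chains.

    Mono-exonic transcripts have no chain and are never chain-equal.
    """
    ka, kb = chain_key(a), chain_key(b)
    return ka is not None and ka == kb


def exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total genomic bases covered by exons of both transcripts.

    Strand-blind by design; callers impose a strand policy. Exons within one
    transcript are disjoint, so a sorted two-pointer merge counts each shared
    base exactly once.
    """
    if a.chrom != b.chrom:
        return 0
    total = 0
    i = j = 0
    while i < a.n_exons and j < b.n_exons:
        ea, eb = a.exons[i], b.exons[j]
        lo, hi = max(ea.start, eb.start), min(ea.end, eb.end)
        if hi > lo:
            total += hi - lo
        if ea.end <= eb.end:
            i += 1
        else:
            j += 1
    return total


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_components(
    transcripts: Sequence[TranscriptModel], stranded: bool
) -> list[list[int]]:
    """Indices of single-linkage components under >=1 bp exonic overlap.

    Sorted-endpoint sweep per (chrom[, strand]) group: exons are visited in
    start order and any exon starting before the running maximum end of the
    current chain overlaps something already in it, which is exactly interval
    connectivity. O(n log n) in the number of exons; identical results to
    brute-force union-find over the all-pairs overlap matrix.
    """
    uf = _UnionFind(len(transcripts))
    groups: dict[tuple, list[tuple[int, int, int]]] = {}
    for idx, t in enumerate(transcripts):
        key = (t.chrom, t.strand) if stranded else (t.chrom,)
        bucket = groups.setdefault(key, [])
        for e in t.exons:
            bucket.append((e.start, e.end, idx))
    for bucket in groups.values():
        bucket.sort()
        chain_end = -1
        rep = -1
        for start, end, idx in bucket:
            if start < chain_end:
                uf.union(idx, rep)
                rep = uf.find(idx)
                chain_end = max(chain_end, end)
            else:
                rep = idx
                chain_end = end
    components: dict[int, list[int]] = {}
    for idx in range(len(transcripts)):
        components.setdefault(uf.find(idx), []).append(idx)
    return list(components.values())


def cluster_loci(
    transcripts: Iterable[TranscriptModel],
    stranded: bool = True,
    gene_id_prefix: str = "XLOC",
) -> list[GeneLocus]:
    """Group transcripts into gene loci by single-linkage exonic overlap.

    Component ids are deterministic: loci are numbered by (chrom, min start,
    strand), so the result is invariant under input permutation.
    """
    txs = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    components = cluster_components(txs, stranded=stranded)
    keyed = sorted(
        components,
        key=lambda comp: (
            txs[comp[0]].chrom,
            min(txs[i].start for i in comp),
            txs[comp[0]].strand,
            txs[comp[0]].transcript_id,
        ),
    )
    loci = []
    for n, comp in enumerate(keyed, start=1):
        gene_id = f"{gene_id_prefix}_{n:06d}"
        loci.append(
            GeneLocus(
                gene_id=gene_id,
                transcripts=tuple(txs[i].with_ids(txs[i].transcript_id, gene_id) for i in comp),
            )
        )
    return loci
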