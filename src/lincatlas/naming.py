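"""Naming of novel lincRNA genes after their nearest protein-coding gene.

Internal locus ids (XLOC-style) and transcript ids (TCONS-style) are replaced
with names built from the nearest protein-coding gene, irrespective of that
gene's strand for the *choice* of neighbor:

    linc-<nearest gene>-<up|down>-<sense|antisense>_<counter>

* ``up``/``down``: whether the lincRNA lies 5' or 3' of the coding gene's
  transcription start, judged in the coding gene's orientation using the
  lincRNA locus midpoint;
* ``sense``/``antisense``: strand concordance between the lincRNA and the
  coding gene;
* the counter distinguishes lincRNAs sharing the same full name stem,
  numbered 1.. in (chromosome, span start) order.

Distance is the span-to-span gap (0 when spans overlap, e.g. a lincRNA
inside a coding gene's intron); ties are broken by the lexicographically
smallest gene name. Transcripts are renamed ``<gene name>:<k>`` with k
numbered by (start, end) within the gene. The renaming is a bijection and is
invariant under any permutation of the input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .model import (
    GeneLocus,
    NamingError,
    TranscriptCatalog,
    TranscriptModel,
)

NAME_RE = re.compile(r"^linc-(?P<gene>.+)-(?P<pos>up|down)-(?P<conc>sense|antisense)_(?P<n>[1-9]\d*)$")


@dataclass(frozen=True)
class NamingRecord:
    linc_gene_id: str
    nearest_gene: str
    distance: int
    position_tag: str
    concordance_tag: str
    counter: int
    old_id: str


def span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in nucleotides between two spans; 0 when they overlap or touch."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def coding_loci(reference: TranscriptCatalog, biotype_attr: str = "gene_biotype",
                coding_value: str = "protein_coding") -> list[GeneLocus]:
    """Loci whose transcripts carry the protein-coding biotype attribute."""
    return [
        locus
        for locus in reference.loci
        if any(t.attributes.get(biotype_attr) == coding_value for t in locus.transcripts)
    ]


def nearest_coding_gene(
    locus: GeneLocus, coding: list[GeneLocus] | TranscriptCatalog
) -> tuple[GeneLocus, int, str]:
    """The nearest coding gene on the locus's chromosome, by span gap.

    Returns the gene, the gap distance, and the genomic flank of the coding
    gene the lincRNA midpoint lies on ('left', 'right', or 'inside'). Ties go
    to the lexicographically smallest gene name. Raises
    :class:`NamingError` when the chromosome has no coding gene.
    """
    if isinstance(coding, TranscriptCatalog):
        coding = list(coding.loci)
    span = locus.span
    candidates = [g for g in coding if g.chrom == span.chrom]
    if not candidates:
        raise NamingError(
            f"no protein-coding gene on chromosome {span.chrom!r} to name "
            f"locus {locus.gene_id!r}"
        )
    best = min(
        candidates,
        key=lambda g: (
            span_gap(span.start, span.end, g.span.start, g.span.end),
            g.gene_id,
        ),
    )
    distance = span_gap(span.start, span.end, best.span.start, best.span.end)
    midpoint = (span.start + span.end) // 2
    if midpoint < best.span.start:
        side = "left"
    elif midpoint >= best.span.end:
        side = "right"
    else:
        side = "inside"
    return best, distance, side


def orientation_tags(locus: GeneLocus, coding_gene: GeneLocus) -> tuple[str, str]:
    """(up|down, sense|antisense) of a lincRNA relative to a coding gene.

    The lincRNA midpoint decides up/down against the coding gene's
    transcription start (span start on '+', span end on '-'). Unstranded
    loci cannot receive a concordance tag and are a naming error.
    """
    if locus.strand not in ("+", "-"):
        raise NamingError(
            f"locus {locus.gene_id!r} has unknown strand and cannot be named"
        )
    if coding_gene.strand not in ("+", "-"):
        raise NamingError(
            f"coding gene {coding_gene.gene_id!r} has unknown strand"
        )
    span = locus.span
    midpoint = (span.start + span.end) // 2
    gspan = coding_gene.span
    if coding_gene.strand == "+":
        position = "up" if midpoint < gspan.start else "down"
    else:
        position = "up" if midpoint >= gspan.end else "down"
    concordance = "sense" if locus.strand == coding_gene.strand else "antisense"
    return position, concordance


def assign_names(
    catalog: TranscriptCatalog, coding: TranscriptCatalog | list[GeneLocus]
) -> tuple[TranscriptCatalog, list[NamingRecord]]:
    """Rename every locus per the naming grammar; return the mapping.

    Counters start at 1 per (nearest gene, position, concordance) stem,
    assigned in (chromosome, span start) order, so names are deterministic
    under any input permutation.
    """
    if isinstance(coding, TranscriptCatalog):
        coding = list(coding.loci)
    ordered = sorted(catalog.loci, key=lambda l: (l.chrom, l.span.start, l.gene_id))
    stems: list[tuple[GeneLocus, str, int, str, str]] = []
    for locus in ordered:
        gene, distance, _side = nearest_coding_gene(locus, coding)
        position, concordance = orientation_tags(locus, gene)
        stems.append((locus, gene.gene_id, distance, position, concordance))
    counters: dict[tuple[str, str, str], int] = {}
    records: list[NamingRecord] = []
    new_loci: list[GeneLocus] = []
    provenance: dict[str, frozenset[str]] = {}
    seen_names: set[str] = set()
    for locus, gene_name, distance, position, concordance in stems:
        key = (gene_name, position, concordance)
        counters[key] = counters.get(key, 0) + 1
        name = f"linc-{gene_name}-{position}-{concordance}_{counters[key]}"
        if name in seen_names:  # cannot happen: counters are per-stem
            raise NamingError(f"duplicate name {name!r}")
        seen_names.add(name)
        records.append(
            NamingRecord(
                linc_gene_id=name,
                nearest_gene=gene_name,
                distance=distance,
                position_tag=position,
                concordance_tag=concordance,
                counter=counters[key],
                old_id=locus.gene_id,
            )
        )
        renamed: list[TranscriptModel] = []
        members = sorted(
            locus.transcripts, key=lambda t: (t.start, t.end, t.transcript_id)
        )
        for k, t in enumerate(members, start=1):
            new_t = t.with_ids(f"{name}:{k}", name)
            renamed.append(new_t)
            provenance[new_t.transcript_id] = catalog.transcript_provenance(
                t.transcript_id
            )
        new_loci.append(GeneLocus(gene_id=name, transcripts=tuple(renamed)))
    return (
        TranscriptCatalog(loci=tuple(new_loci), provenance=provenance),
        records,
    )


def write_name_mapping(records: list[NamingRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "old_id": r.old_id,
                "new_name": r.linc_gene_id,
                "nearest_gene": r.nearest_gene,
                "distance": r.distance,
                "position": r.position_tag,
                "concordance": r.concordance_tag,
                "counter": r.counter,
            }
            for r in records
        ],
        columns=[
            "old_id",
            "new_name",
            "nearest_gene",
            "distance",
            "position",
            "concordance",
            "counter",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_name_mapping(path: str | Path) -> list[NamingRecord]:
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    return [
        NamingRecord(
            linc_gene_id=row.new_name,
            nearest_gene=row.nearest_gene,
            distance=int(row.distance),
            position_tag=row.position,
            concordance_tag=row.concordance,
            counter=int(row.counter),
            old_id=row.old_id,
        )
        for row in table.itertuples()
    ]
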