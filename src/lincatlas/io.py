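"""Readers and writers for GTF catalogs, score tables, FPKM tables, FASTA.

GTF files are 1-based inclusive; everything in memory is 0-based half-open.
Only ``exon`` features are consumed: transcript/gene/CDS lines are skipped
with a debug log, since the catalogs this pipeline exchanges are exon-line
GTFs. Writing then reading a catalog reproduces it exactly, including
pass-through attributes and per-transcript provenance (serialized as a
``supporting_methods`` attribute).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .model import (
    CodingScoreTable,
    ExpressionMatrix,
    GeneLocus,
    GenomeInterval,
    GtfParseError,
    ModelValidationError,
    TranscriptCatalog,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_PROVENANCE_ATTR = "supporting_methods"
_RESERVED_ATTRS = ("gene_id", "transcript_id", _PROVENANCE_ATTR)


def _parse_attributes(field: str, path: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field))
    if "gene_id" not in attrs or "transcript_id" not in attrs:
        raise GtfParseError(
            f"{path}:{lineno}: exon line missing gene_id or transcript_id "
            f"attribute: {field!r}"
        )
    return attrs


def read_gtf(path: str | Path) -> TranscriptCatalog:
    """Read an exon-line GTF into a catalog grouped by gene_id.

    Raises :class:`GtfParseError` with the offending line number on malformed
    lines, and :class:`ModelValidationError` on structurally invalid
    transcripts (mixed chromosomes/strands, overlapping exons).
    """
    path = Path(path)
    exons: dict[str, list[GenomeInterval]] = {}
    gene_of: dict[str, str] = {}
    attrs_of: dict[str, dict[str, str]] = {}
    provenance: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"found {len(cols)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = cols
            if feature != "exon":
                logger.debug("%s:%d: skipping %s feature", path, lineno, feature)
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}, {end_s!r}"
                ) from None
            if end1 < start1 or start1 < 1:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid coordinates {start1}..{end1}"
                )
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_s, str(path), lineno)
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            if tid in gene_of and gene_of[tid] != gid:
                raise ModelValidationError(
                    f"{path}:{lineno}: transcript {tid!r} assigned to both "
                    f"genes {gene_of[tid]!r} and {gid!r}"
                )
            gene_of[tid] = gid
            # 1-based inclusive -> 0-based half-open
            exons.setdefault(tid, []).append(
                GenomeInterval(chrom, start1 - 1, end1, strand)
            )
            extra = {k: v for k, v in attrs.items() if k not in _RESERVED_ATTRS}
            attrs_of.setdefault(tid, {}).update(extra)
            if _PROVENANCE_ATTR in attrs and attrs[_PROVENANCE_ATTR]:
                provenance[tid] = frozenset(attrs[_PROVENANCE_ATTR].split(","))

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, tx_exons in exons.items():
        try:
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of[tid],
                exons=tuple(tx_exons),
                attributes=attrs_of.get(tid, {}),
            )
        except ModelValidationError as exc:
            raise ModelValidationError(f"{path}: {exc}") from None
        by_gene.setdefault(gene_of[tid], []).append(model)

    loci = tuple(
        GeneLocus(gene_id=gid, transcripts=tuple(txs))
        for gid, txs in by_gene.items()
    )
    return TranscriptCatalog(loci=loci, provenance=provenance)


def _format_attributes(t: TranscriptModel, provenance: frozenset[str]) -> str:
    parts = [f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";']
    for key in sorted(t.attributes):
        parts.append(f'{key} "{t.attributes[key]}";')
    if provenance:
        parts.append(f'{_PROVENANCE_ATTR} "{",".join(sorted(provenance))}";')
    return " ".join(parts)


def write_gtf(catalog: TranscriptCatalog, path: str | Path) -> None:
    """Write a catalog as a sorted, exon-line GTF (1-based inclusive)."""
    records = sorted(
        catalog.transcripts(), key=lambda t: (t.chrom, t.start, t.transcript_id)
    )
    with open(path, "w") as handle:
        for t in records:
            attr_s = _format_attributes(t, catalog.transcript_provenance(t.transcript_id))
            for exon in t.exons:
                handle.write(
                    "\t".join(
                        (
                            t.chrom,
                            "lincatlas",
                            "exon",
                            str(exon.start + 1),  # back to 1-based inclusive
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            attr_s,
                        )
                    )
                    + "\n"
                )


def read_coding_scores(path: str | Path) -> CodingScoreTable:
    """Read a two-column TSV of transcript_id and coding score (decibans)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        return CodingScoreTable(scores={})
    if not {"transcript_id", "score"} <= set(table.columns):
        raise GtfParseError(
            f"{path}: expected columns 'transcript_id' and 'score', "
            f"found {list(table.columns)}"
        )
    scores = pd.to_numeric(table["score"], errors="coerce")
    bad = table.loc[scores.isna() & table["score"].notna(), "transcript_id"]
    if len(bad) or scores.isna().any():
        raise GtfParseError(f"{path}: non-numeric score for {list(bad)[:5]}")
    dupes = table["transcript_id"][table["transcript_id"].duplicated()]
    if len(dupes):
        raise ModelValidationError(
            f"{path}: duplicate transcript ids {sorted(set(dupes))[:5]}"
        )
    return CodingScoreTable(
        scores=dict(zip(table["transcript_id"], scores.astype(float)))
    )


def write_coding_scores(scores: CodingScoreTable, path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(scores.scores), "score": list(scores.scores.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a gene x population FPKM TSV (first column = gene id)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise GtfParseError(f"{path}: {exc}") from None
    except pd.errors.EmptyDataError:
        import numpy as np

        return ExpressionMatrix(genes=(), populations=(), values=np.empty((0, 0)))
    if table.isna().any().any():
        raise GtfParseError(f"{path}: missing or non-numeric FPKM cell")
    try:
        values = table.to_numpy(dtype=float)
    except ValueError as exc:
        raise GtfParseError(f"{path}: non-numeric FPKM value: {exc}") from None
    return ExpressionMatrix(
        genes=tuple(str(g) for g in table.index),
        populations=tuple(str(p) for p in table.columns),
        values=values,
    )


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.values, index=list(matrix.genes), columns=list(matrix.populations)
    ).to_csv(path, sep="\t", index_label="gene_id")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences into a transcript_id -> sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
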