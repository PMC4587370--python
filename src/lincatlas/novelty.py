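"""Novelty classification of candidate transcripts against a reference.

Each candidate is compared with the merged reference annotation and labeled:

* ``known`` — its intron chain is identical to a reference transcript's;
* ``novel_isoform`` — it shares >= 1 exonic base with a reference transcript
  but is not chain-equal (this includes antisense-exonic overlaps under the
  default strand policy, which are genic and therefore not intergenic);
* ``intergenic_novel`` — zero exonic overlap with every reference transcript
  under the configured strand policy.

Only ``intergenic_novel`` transcripts enter the lincRNA filter cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .algebra import chain_key, cluster_loci, exonic_overlap_bp
from .model import (
    ModelValidationError,
    PipelineConfig,
    TranscriptCatalog,
    TranscriptModel,
    empty_catalog,
)

logger = logging.getLogger(__name__)


class NoveltyLabel(str, Enum):
    KNOWN = "known"
    NOVEL_ISOFORM = "novel_isoform"
    INTERGENIC_NOVEL = "intergenic_novel"


@dataclass(frozen=True)
class NoveltyClass:
    label: NoveltyLabel
    evidence: str | None = None  # matched reference transcript id, when any


class ReferenceIndex:
    """Interval-tree index of reference exons plus an intron-chain lookup."""

    def __init__(self, reference: TranscriptCatalog) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._chains: dict = {}
        self._transcripts: list[TranscriptModel] = []
        for t in reference.transcripts():
            idx = len(self._transcripts)
            self._transcripts.append(t)
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            for e in t.exons:
                tree.addi(e.start, e.end, idx)
            key = chain_key(t)
            if key is not None:
                self._chains.setdefault(key, t.transcript_id)

    def chain_match(self, t: TranscriptModel) -> str | None:
        key = chain_key(t)
        return self._chains.get(key) if key is not None else None

    def overlapping(self, t: TranscriptModel) -> Iterable[TranscriptModel]:
        """Reference transcripts with >= 1 bp exonic overlap (strand-blind)."""
        tree = self._trees.get(t.chrom)
        if tree is None:
            return []
        hits: set[int] = set()
        for e in t.exons:
            hits.update(iv.data for iv in tree.overlap(e.start, e.end))
        return sorted(
            (self._transcripts[i] for i in hits),
            key=lambda r: (r.start, r.transcript_id),
        )


def _strands_concordant(a: TranscriptModel, b: TranscriptModel) -> bool:
    # an unstranded candidate cannot be excluded from a same-strand overlap
    return a.strand == b.strand or a.strand == "." or b.strand == "."


def classify_transcript(
    candidate: TranscriptModel,
    reference: TranscriptCatalog | ReferenceIndex,
    config: PipelineConfig | None = None,
) -> NoveltyClass:
    """Classify one candidate against the reference annotation.

    With ``config.intergenic_stranded`` False (default), exonic overlap on
    either strand disqualifies a candidate from ``intergenic_novel``; with
    True, only same-strand overlap counts and antisense overlaps are treated
    as intergenic.
    """
    config = config or PipelineConfig()
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    matched = index.chain_match(candidate)
    if matched is not None:
        return NoveltyClass(NoveltyLabel.KNOWN, evidence=matched)
    same_strand_hit: str | None = None
    any_hit: str | None = None
    for ref in index.overlapping(candidate):
        if exonic_overlap_bp(candidate, ref) < 1:
            continue
        if any_hit is None:
            any_hit = ref.transcript_id
        if _strands_concordant(candidate, ref):
            same_strand_hit = ref.transcript_id
            break
    if same_strand_hit is not None:
        return NoveltyClass(NoveltyLabel.NOVEL_ISOFORM, evidence=same_strand_hit)
    if any_hit is not None and not config.intergenic_stranded:
        # genic on the opposite strand: not intergenic under the default policy
        return NoveltyClass(NoveltyLabel.NOVEL_ISOFORM, evidence=any_hit)
    return NoveltyClass(NoveltyLabel.INTERGENIC_NOVEL)


def merge_annotations(
    primary: TranscriptCatalog, secondary: TranscriptCatalog
) -> TranscriptCatalog:
    """Integrate a secondary annotation into a primary one.

    Secondary transcripts that are chain-equal to a primary transcript are
    redundant and dropped (the primary id wins); the union is re-clustered
    into stranded loci.
    """
    primary_txs = list(primary.transcripts())
    primary_chains = {chain_key(t) for t in primary_txs} - {None}
    primary_ids = {t.transcript_id: t for t in primary_txs}
    merged = list(primary_txs)
    for t in secondary.transcripts():
        if t.transcript_id in primary_ids:
            if primary_ids[t.transcript_id].exons != t.exons:
                raise ModelValidationError(
                    f"transcript id {t.transcript_id!r} maps to different "
                    "models in the two annotations"
                )
            continue
        if chain_key(t) in primary_chains:
            logger.debug("dropping redundant secondary transcript %s", t.transcript_id)
            continue
        merged.append(t)
    loci = cluster_loci(merged, stranded=True, gene_id_prefix="MRG")
    provenance = {**dict(secondary.provenance), **dict(primary.provenance)}
    return TranscriptCatalog(loci=tuple(loci), provenance=provenance)


def classify_catalog(
    candidates: TranscriptCatalog,
    reference: TranscriptCatalog,
    config: PipelineConfig | None = None,
) -> dict[str, NoveltyClass]:
    index = ReferenceIndex(reference)
    return {
        t.transcript_id: classify_transcript(t, index, config)
        for t in candidates.transcripts()
    }


def filter_intergenic(
    candidates: TranscriptCatalog,
    reference: TranscriptCatalog,
    config: PipelineConfig | None = None,
    log_path: str | Path | None = None,
) -> TranscriptCatalog:
    """Retain only intergenic novel transcripts, re-clustered into loci."""
    classes = classify_catalog(candidates, reference, config)
    if log_path is not None:
        write_classification_log(classes, log_path)
    survivors = [
        t
        for t in candidates.transcripts()
        if classes[t.transcript_id].label is NoveltyLabel.INTERGENIC_NOVEL
    ]
    for tid, cls in classes.items():
        if cls.label is not NoveltyLabel.INTERGENIC_NOVEL:
            logger.debug(
                "novelty filter removed %s (%s, evidence=%s)",
                tid,
                cls.label.value,
                cls.evidence,
            )
    if not survivors:
        return empty_catalog()
    loci = cluster_loci(survivors, stranded=True)
    return TranscriptCatalog(
        loci=tuple(loci),
        provenance={
            t.transcript_id: candidates.transcript_provenance(t.transcript_id)
            for t in survivors
        },
    )


def write_classification_log(
    classes: dict[str, NoveltyClass], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "transcript_id": list(classes),
            "class": [c.label.value for c in classes.values()],
            "evidence_id": [c.evidence or "" for c in classes.values()],
        }
    ).to_csv(path, sep="\t", index=False)
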