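"""Structural and coding-potential filters for intergenic candidates.

The cascade removes, in any order (the filters commute):

* transcripts that are mono-exonic or whose mature length is not strictly
  greater than 200 nt — short single-exon fragments are the signature of
  transcriptional noise and polymerase infidelity;
* transcripts with a protein-domain hit in any of their six translation
  frames (three forward, three reverse-complement);
* transcripts whose coding-potential score exceeds 100 decibans — the
  PhyloCSF-convention log-odds cutoff above which a transcript is treated as
  protein-coding. A score of exactly 100 is retained.

Domain searching is abstracted as a :class:`DomainMatcher` predicate so the
cascade runs without an external profile-HMM engine; any deterministic
peptide -> bool callable (for example a wrapper around an external search)
plugs in. :class:`MotifMatcher` is a literal-substring implementation used
for testing and synthetic data.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Mapping, Protocol

from Bio.Seq import Seq

from .model import (
    GeneLocus,
    ModelValidationError,
    PipelineConfig,
    CodingScoreTable,
    TranscriptCatalog,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGTN")


class DomainMatcher(Protocol):
    """Deterministic, stateless predicate: peptide string -> hit flag."""

    def __call__(self, peptide: str) -> bool: ...


class MotifMatcher:
    """Exact-substring domain matcher over a list of literal peptide motifs."""

    def __init__(self, motifs: list[str]) -> None:
        self.motifs = [m.strip().upper() for m in motifs if m.strip()]

    @classmethod
    def from_file(cls, path: str | Path) -> "MotifMatcher":
        with open(path) as handle:
            return cls(handle.read().splitlines())

    def __call__(self, peptide: str) -> bool:
        return any(m in peptide for m in self.motifs)


def never_matcher(peptide: str) -> bool:
    return False


def six_frame_translate(sequence: str) -> tuple[str, str, str, str, str, str]:
    """Translate all six reading frames with the standard genetic code.

    Frames 0-2 are the forward strand at offsets 0, 1, 2; frames 3-5 are the
    reverse complement at offsets 0, 1, 2. Stops are rendered ``*``, fully
    ambiguous codons ``X``; trailing partial codons are dropped.
    """
    sequence = sequence.upper()
    bad = set(sequence) - _NUCLEOTIDES
    if bad:
        raise ModelValidationError(
            f"sequence contains characters outside ACGTN: {sorted(bad)}"
        )
    fwd = Seq(sequence)
    rev = fwd.reverse_complement()
    frames = []
    for strand_seq in (fwd, rev):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate()))
    return tuple(frames)  # type: ignore[return-value]


def _rebuild(
    catalog: TranscriptCatalog, keep: Callable[[TranscriptModel], bool]
) -> TranscriptCatalog:
    """Drop transcripts failing ``keep``; drop loci left empty; keep ids."""
    new_loci = []
    kept_ids = set()
    for locus in catalog.loci:
        survivors = tuple(t for t in locus.transcripts if keep(t))
        if survivors:
            new_loci.append(GeneLocus(gene_id=locus.gene_id, transcripts=survivors))
            kept_ids.update(t.transcript_id for t in survivors)
    return TranscriptCatalog(
        loci=tuple(new_loci),
        provenance={k: v for k, v in catalog.provenance.items() if k in kept_ids},
    )


def filter_structural(
    catalog: TranscriptCatalog, config: PipelineConfig | None = None
) -> TranscriptCatalog:
    """Keep multi-exonic transcripts with mature length > 200 nt.

    Both boundaries are strict in the sense of the published rule: exon
    count >= ``min_exons`` (default 2) and mature length >=
    ``min_transcript_length`` (default 201, i.e. strictly longer than 200).
    """
    from .algebra import transcript_length

    config = config or PipelineConfig()

    def keep(t: TranscriptModel) -> bool:
        ok = (
            t.n_exons >= config.min_exons
            and transcript_length(t) >= config.min_transcript_length
        )
        if not ok:
            logger.debug(
                "structural filter removed %s (exons=%d, length=%d)",
                t.transcript_id,
                t.n_exons,
                transcript_length(t),
            )
        return ok

    return _rebuild(catalog, keep)


def filter_domain_hits(
    catalog: TranscriptCatalog,
    sequences: Mapping[str, str],
    matcher: DomainMatcher,
    log_path: str | Path | None = None,
) -> TranscriptCatalog:
    """Discard transcripts with a domain hit in >= 1 of their 6 frames."""
    hits: dict[str, bool] = {}
    for t in catalog.transcripts():
        if t.transcript_id not in sequences:
            raise ModelValidationError(
                f"no sequence provided for transcript {t.transcript_id!r}"
            )
        frames = six_frame_translate(sequences[t.transcript_id])
        hits[t.transcript_id] = any(matcher(p) for p in frames)
        if hits[t.transcript_id]:
            logger.debug("domain filter removed %s", t.transcript_id)
    if log_path is not None:
        import pandas as pd

        pd.DataFrame(
            {"transcript_id": list(hits), "domain_hit": [int(h) for h in hits.values()]}
        ).to_csv(log_path, sep="\t", index=False)
    return _rebuild(catalog, lambda t: not hits[t.transcript_id])


def filter_coding_potential(
    catalog: TranscriptCatalog,
    scores: CodingScoreTable,
    config: PipelineConfig | None = None,
) -> TranscriptCatalog:
    """Exclude transcripts scoring strictly more than the coding cutoff.

    A score equal to the cutoff (100 decibans by default) is retained. With
    ``config.strict_scores`` (default) a transcript without a score is an
    error; otherwise it is assumed non-coding and the assumption is logged.
    """
    config = config or PipelineConfig()

    def keep(t: TranscriptModel) -> bool:
        if t.transcript_id not in scores:
            if config.strict_scores:
                raise ModelValidationError(
                    f"no coding score for transcript {t.transcript_id!r}"
                )
            logger.warning(
                "no coding score for %s; assuming non-coding", t.transcript_id
            )
            return True
        excluded = scores[t.transcript_id] > config.coding_score_cutoff
        if excluded:
            logger.debug(
                "coding filter removed %s (score=%.2f)",
                t.transcript_id,
                scores[t.transcript_id],
            )
        return not excluded

    return _rebuild(catalog, keep)
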