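"""Core domain types for transcript catalogs.

All coordinates are 0-based, half-open ``[start, end)``. The GTF boundary in
:mod:`lincatlas.io` converts to and from the 1-based inclusive convention of
the file format, so interval arithmetic everywhere else is free of off-by-one
adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

STRAND_FWD = "+"
STRAND_REV = "-"
STRAND_UNKNOWN = "."

_VALID_STRANDS = frozenset({STRAND_FWD, STRAND_REV, STRAND_UNKNOWN})


class LincAtlasError(Exception):
    """Base class for all errors raised by this package."""


class GtfParseError(LincAtlasError):
    """A malformed line in a GTF or tabular input file."""


class ModelValidationError(LincAtlasError):
    """A structurally invalid transcript, catalog, or matrix."""


class NamingError(LincAtlasError):
    """A locus that cannot receive a name under the naming grammar."""


class PipelineError(LincAtlasError):
    """A stage-level failure during pipeline orchestration."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ModelValidationError(
                f"invalid strand {self.strand!r} (expected one of +, -, .)"
            )
        if self.start < 0 or self.end <= self.start:
            raise ModelValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True when the two intervals share >= 1 base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered, disjoint exon list on a single strand.

    ``attributes`` carries pass-through GTF attributes (for example
    ``gene_biotype``) that the pipeline preserves but does not interpret,
    except where documented (reference biotypes in naming).
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomeInterval, ...]
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelValidationError(
                f"transcript {self.transcript_id!r} has no exons"
            )
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ModelValidationError(
                f"transcript {self.transcript_id!r} mixes chromosomes or "
                f"strands: {sorted(chroms)}, {sorted(strands)}"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ModelValidationError(
                    f"transcript {self.transcript_id!r} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "attributes", dict(self.attributes))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def with_ids(self, transcript_id: str, gene_id: str) -> "TranscriptModel":
        return replace(self, transcript_id=transcript_id, gene_id=gene_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptModel):
            return NotImplemented
        return (
            self.transcript_id == other.transcript_id
            and self.gene_id == other.gene_id
            and self.exons == other.exons
            and dict(self.attributes) == dict(other.attributes)
        )

    def __hash__(self) -> int:
        return hash((self.transcript_id, self.gene_id, self.exons))


@dataclass(frozen=True)
class GeneLocus:
    """A gene-level grouping of transcripts on one chromosome and strand."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelValidationError(f"locus {self.gene_id!r} is empty")
        txs = tuple(
            sorted(self.transcripts, key=lambda t: (t.start, t.end, t.transcript_id))
        )
        object.__setattr__(self, "transcripts", txs)
        if len({t.chrom for t in txs}) > 1:
            raise ModelValidationError(
                f"locus {self.gene_id!r} mixes chromosomes"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        # '.' for the mixed-strand loci unstranded clustering can produce
        strands = {t.strand for t in self.transcripts}
        return self.transcripts[0].strand if len(strands) == 1 else "."

    @property
    def span(self) -> GenomeInterval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomeInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class TranscriptCatalog:
    """A set of loci with per-transcript source-method provenance."""

    loci: tuple[GeneLocus, ...]
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loci = tuple(
            sorted(self.loci, key=lambda l: (l.chrom, l.span.start, l.gene_id))
        )
        object.__setattr__(self, "loci", loci)
        seen: set[str] = set()
        for locus in loci:
            for t in locus.transcripts:
                if t.transcript_id in seen:
                    raise ModelValidationError(
                        f"duplicate transcript_id {t.transcript_id!r} in catalog"
                    )
                seen.add(t.transcript_id)
        object.__setattr__(
            self,
            "provenance",
            {k: frozenset(v) for k, v in self.provenance.items() if k in seen},
        )

    def transcripts(self) -> Iterator[TranscriptModel]:
        for locus in self.loci:
            yield from locus.transcripts

    @property
    def n_genes(self) -> int:
        return len(self.loci)

    @property
    def n_transcripts(self) -> int:
        return sum(len(l.transcripts) for l in self.loci)

    def transcript_provenance(self, transcript_id: str) -> frozenset[str]:
        return self.provenance.get(transcript_id, frozenset())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptCatalog):
            return NotImplemented
        return self.loci == other.loci and dict(self.provenance) == dict(
            other.provenance
        )

    def __hash__(self) -> int:
        return hash(self.loci)


def empty_catalog() -> TranscriptCatalog:
    return TranscriptCatalog(loci=())


@dataclass
class PipelineConfig:
    """All discovery thresholds in one place.

    Defaults encode the published filter cascade: mature length strictly
    greater than 200 nt, at least 2 exons, coding-potential exclusion strictly
    above 100 decibans, gene support by at least 2 of 3 reconstruction
    methods, and an inclusive 0.21 FPKM expression floor.
    """

    min_transcript_length: int = 201  # keep length >= 201, i.e. strictly > 200
    min_exons: int = 2
    coding_score_cutoff: float = 100.0  # exclude score strictly greater
    min_methods: int = 2
    n_methods: int = 3
    expression_floor: float = 0.21  # keep max FPKM >= floor (inclusive)
    intergenic_stranded: bool = False  # False: overlap on either strand disqualifies
    expression_inclusive: bool = True
    strict_scores: bool = True
    strict_expression: bool = True
    consensus_support: str = "locus"  # or "chain": 2-of-3 on chain-equal transcripts

    def __post_init__(self) -> None:
        if min(
            self.min_transcript_length,
            self.min_exons,
            self.coding_score_cutoff,
            self.min_methods,
            self.n_methods,
            self.expression_floor,
        ) <= 0:
            raise ModelValidationError("all thresholds must be positive")
        if self.min_methods > self.n_methods:
            raise ModelValidationError("min_methods cannot exceed n_methods")
        if self.consensus_support not in ("locus", "chain"):
            raise ModelValidationError(
                f"consensus_support must be 'locus' or 'chain', got "
                f"{self.consensus_support!r}"
            )


@dataclass(frozen=True)
class CodingScoreTable:
    """Per-transcript coding-potential scores in decibans (may be negative)."""

    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", dict(self.scores))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.scores

    def __getitem__(self, transcript_id: str) -> float:
        return self.scores[transcript_id]

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x population FPKM values (non-negative)."""

    genes: tuple[str, ...]
    populations: tuple[str, ...]
    values: "object"  # numpy array, shape (n_genes, n_populations)

    def __post_init__(self) -> None:
        import numpy as np

        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.genes), len(self.populations)):
            raise ModelValidationError(
                f"expression matrix shape {values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.populations)} populations"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ModelValidationError("duplicate gene ids in expression matrix")
        if values.size and values.min() < 0:
            raise ModelValidationError("negative FPKM value in expression matrix")
        object.__setattr__(
            self, "_gene_index", {g: i for i, g in enumerate(self.genes)}
        )

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def row(self, gene_id: str):
        return self.values[self._gene_index[gene_id]]

    def max_fpkm(self, gene_id: str) -> float:
        return float(self.row(gene_id).max())
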