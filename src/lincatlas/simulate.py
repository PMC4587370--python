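"""Seeded synthetic input bundles with known ground truth.

The generator emulates the data a de novo lincRNA discovery run consumes —
a reference annotation of protein-coding and known-lincRNA genes, three
noisy per-method transcript catalogs, per-transcript coding scores and
sequences, and a gene x population FPKM table — without any sequencing
data. Every quantity is a pure function of :class:`SimulationParams`; named
substreams keep placement, detection, jitter, scores, sequences, and
expression independent of one another, so changing one rate never reshuffles
unrelated draws.

Genome layout
-------------
Coding genes are placed left to right, each followed by a fixed-width
intergenic *slot*. A slot's left zone can host exactly one occupant (a
planted novel lincRNA, a known reference lincRNA, or an intergenic
coding contaminant), placed much closer to the gene on its left than to the
gene on its right; the slot's right zone hosts mono-exonic and sub-200-nt
artifact fragments. Because each planted lincRNA is the only occupant next
to its coding gene, its final name is predictable
(``linc-<gene>-<up|down>-<sense|antisense>_1``) no matter which other
planted genes survive, which lets the FPKM table and the truth table be
keyed by final names.

Artifact classes each target exactly one filter: mono-exonic fragments and
short multi-exonic transcripts die at the structural filter; chain-equal
reassemblies of reference transcripts are classified known; extra-exon
variants of reference genes are classified novel isoforms; intergenic
coding contaminants carry scores above 100 decibans (and, for every second
one, a planted domain motif) and die at the coding-potential or domain
filter. None can reach the final catalog unless a filter is broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .algebra import cluster_loci, transcript_length
from .consensus import MethodCatalog
from .filters import MotifMatcher, six_frame_translate
from .model import (
    CodingScoreTable,
    ExpressionMatrix,
    GeneLocus,
    GenomeInterval,
    LincAtlasError,
    TranscriptCatalog,
    TranscriptModel,
)

# test motif for the naive domain matcher; planted lincRNA sequences are
# regenerated until free of it in all six frames
DOMAIN_MOTIF = "WDHKRFME"
_MOTIF_CODONS = {
    "W": "TGG", "D": "GAT", "H": "CAT", "K": "AAA",
    "R": "CGT", "F": "TTT", "M": "ATG", "E": "GAA",
}
DOMAIN_MOTIF_NT = "".join(_MOTIF_CODONS[aa] for aa in DOMAIN_MOTIF)

_SLOT = 12_000
_OCC_ZONE = (300, 5_300)  # occupant zone, relative to slot start
_ART_ZONE = (7_000, 11_000)  # artifact zone, relative to slot start

# substream tags
_S_LAYOUT, _S_ASSIGN, _S_DETECT, _S_JITTER = 0, 1, 2, 3
_S_SCORES, _S_SEQ, _S_EXPR, _S_ART = 4, 5, 6, 7


class SimulationError(LincAtlasError):
    pass


@dataclass
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults mirror the discovery conditions the pipeline is meant to be
    exercised under: three reconstruction methods with equal 0.8 detection
    probability, 200 planted novel lincRNAs, 13 populations, terminal-end
    jitter of up to 30 nt that never moves a splice site, and artifact
    classes at a fraction of the planted count.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 3_000_000
    n_coding: int = 260
    n_known_linc: int = 20
    n_planted: int = 200
    p_detect: tuple[float, float, float] = (0.8, 0.8, 0.8)
    mono_exonic_rate: float = 0.2
    short_transcript_rate: float = 0.2
    coding_contaminant_rate: float = 0.1
    known_reassembly_rate: float = 0.2
    novel_isoform_rate: float = 0.2
    end_jitter: int = 30
    fraction_below_floor: float = 0.0
    n_populations: int = 13
    method_labels: tuple[str, ...] = (
        "tophat_cufflinks",
        "star_cufflinks",
        "star_trinity_pasa",
    )

    def __post_init__(self) -> None:
        for p in self.p_detect:
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"detection probability {p} outside [0, 1]")
        for r in (
            self.mono_exonic_rate,
            self.short_transcript_rate,
            self.coding_contaminant_rate,
            self.known_reassembly_rate,
            self.novel_isoform_rate,
            self.fraction_below_floor,
        ):
            if not 0.0 <= r <= 1.0:
                raise SimulationError(f"rate {r} outside [0, 1]")
        if self.n_planted < 0 or self.end_jitter < 0:
            raise SimulationError("n_planted and end_jitter must be >= 0")
        if len(self.method_labels) != len(self.p_detect):
            raise SimulationError("one detection probability per method required")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])

    @property
    def n_contaminants(self) -> int:
        return int(round(self.coding_contaminant_rate * self.n_planted))


@dataclass
class _Slot:
    chrom: str
    start: int  # absolute slot start (= left gene end, or grid position)
    left_gene: str | None  # gene_id of the coding gene on the left
    left_gene_strand: str | None
    occupant: str | None = None  # "planted:<i>" | "known_linc:<i>" | "contaminant:<i>"


@dataclass
class _Layout:
    coding: list[TranscriptModel]
    known_lincs: list[TranscriptModel]
    planted: list[TranscriptModel]
    contaminants: list[TranscriptModel]
    slots: list[_Slot]
    expected_names: dict[str, str]  # planted gene_id -> predicted final name


def _make_gene_model(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    strand: str,
    transcript_id: str,
    gene_id: str,
    n_exons_range: tuple[int, int],
    exon_len_range: tuple[int, int],
    intron_len_range: tuple[int, int],
    attributes: dict[str, str],
    min_length: int = 0,
) -> TranscriptModel:
    n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_exons)
    if min_length and exon_lens.sum() < min_length:
        exon_lens[-1] += min_length - int(exon_lens.sum())
    intron_lens = rng.integers(
        intron_len_range[0], intron_len_range[1] + 1, size=max(n_exons - 1, 0)
    )
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(GenomeInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        exons=tuple(exons),
        attributes=attributes,
    )


def _build_layout(params: SimulationParams) -> _Layout:
    rng_layout = params.rng(_S_LAYOUT)
    rng_assign = params.rng(_S_ASSIGN)

    n_occupants = params.n_planted + params.n_known_linc + params.n_contaminants
    n_slots = max(params.n_coding, n_occupants)

    coding: list[TranscriptModel] = []
    slots: list[_Slot] = []
    chrom_idx, cursor = 0, 1_000
    max_gene_span = 10 * 300 + 9 * 1_500  # geometry upper bound
    for s in range(n_slots):
        if cursor + max_gene_span + _SLOT > params.chrom_length:
            chrom_idx += 1
            cursor = 1_000
        if chrom_idx >= params.n_chroms:
            raise SimulationError(
                f"genome of {params.n_chroms} x {params.chrom_length} nt too "
                f"small for {n_slots} gene slots"
            )
        chrom = f"chr{chrom_idx + 1}"
        if s < params.n_coding:
            strand = "+" if rng_layout.random() < 0.5 else "-"
            gene_id = f"GENE{s:04d}"
            model = _make_gene_model(
                rng_layout, chrom, cursor, strand,
                transcript_id=f"{gene_id}.t1", gene_id=gene_id,
                n_exons_range=(2, 10), exon_len_range=(100, 300),
                intron_len_range=(300, 1_500),
                attributes={"gene_biotype": "protein_coding"},
            )
            coding.append(model)
            slot_start = model.end
            slots.append(_Slot(chrom, slot_start, gene_id, strand))
            cursor = slot_start + _SLOT
        else:
            # gene-less slot (only reachable when occupants outnumber genes)
            rng_layout.random()  # keep the stream aligned with gene slots
            slots.append(_Slot(chrom, cursor, None, None))
            cursor += _SLOT

    # assign occupants: planted lincs need gene-bearing slots for stable names
    order = list(rng_assign.permutation(n_slots))
    gene_bearing = [i for i in order if slots[i].left_gene is not None]
    gene_less = [i for i in order if slots[i].left_gene is None]
    if len(gene_bearing) < params.n_planted:
        raise SimulationError(
            f"{params.n_planted} planted lincRNAs need at least as many "
            f"coding genes; only {len(gene_bearing)} available"
        )
    planted_slots = gene_bearing[: params.n_planted]
    rest = gene_bearing[params.n_planted :] + gene_less
    known_slots = rest[: params.n_known_linc]
    contaminant_slots = rest[
        params.n_known_linc : params.n_known_linc + params.n_contaminants
    ]
    if len(known_slots) < params.n_known_linc or len(contaminant_slots) < params.n_contaminants:
        raise SimulationError("not enough intergenic slots for all occupants")

    def place_occupant(
        slot: _Slot,
        transcript_id: str,
        gene_id: str,
        attributes: dict[str, str],
        min_length: int,
    ) -> TranscriptModel:
        strand = "+" if rng_assign.random() < 0.5 else "-"
        offset = int(rng_assign.integers(0, 501))
        return _make_gene_model(
            rng_assign, slot.chrom, slot.start + _OCC_ZONE[0] + offset, strand,
            transcript_id=transcript_id, gene_id=gene_id,
            n_exons_range=(2, 5), exon_len_range=(100, 250),
            intron_len_range=(150, 800),
            attributes=attributes, min_length=min_length,
        )

    known_lincs = []
    for i, si in enumerate(known_slots):
        gene_id = f"KLINC{i:03d}"
        model = place_occupant(
            slots[si], f"{gene_id}.t1", gene_id,
            {"gene_biotype": "lincRNA"}, min_length=300,
        )
        slots[si].occupant = f"known_linc:{i}"
        known_lincs.append(model)

    planted = []
    expected_names: dict[str, str] = {}
    for i, si in enumerate(planted_slots):
        gene_id = f"PLG{i:04d}"
        model = place_occupant(
            slots[si], f"PL{i:04d}", gene_id, {}, min_length=300
        )
        slots[si].occupant = f"planted:{i}"
        planted.append(model)
        # occupant sits a few hundred nt right of its slot's coding gene, so
        # that gene is its nearest neighbor: downstream of a '+' gene,
        # upstream of a '-' gene; one occupant per gene => counter is 1
        position = "down" if slots[si].left_gene_strand == "+" else "up"
        concordance = (
            "sense" if model.strand == slots[si].left_gene_strand else "antisense"
        )
        expected_names[gene_id] = (
            f"linc-{slots[si].left_gene}-{position}-{concordance}_1"
        )

    contaminants = []
    for i, si in enumerate(contaminant_slots):
        gene_id = f"CCG{i:03d}"
        model = place_occupant(
            slots[si], f"CC{i:03d}", gene_id, {}, min_length=300
        )
        slots[si].occupant = f"contaminant:{i}"
        contaminants.append(model)

    return _Layout(coding, known_lincs, planted, contaminants, slots, expected_names)


def generate_reference(params: SimulationParams) -> TranscriptCatalog:
    """The reference annotation: coding genes plus known lincRNA genes."""
    layout = _build_layout(params)
    loci = [
        GeneLocus(gene_id=t.gene_id, transcripts=(t,))
        for t in layout.coding + layout.known_lincs
    ]
    return TranscriptCatalog(loci=tuple(loci))


def plant_novel_lincs(
    reference: TranscriptCatalog, params: SimulationParams
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """The planted novel lincRNAs and the initial truth table."""
    del reference  # layout is a pure function of params
    layout = _build_layout(params)
    rows = []
    for i, t in enumerate(layout.planted):
        rows.append(
            {
                "planted_id": t.gene_id,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "n_exons": t.n_exons,
                "length": transcript_length(t),
                "expected_name": layout.expected_names[t.gene_id],
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "planted_id", "chrom", "start", "end", "strand",
            "n_exons", "length", "expected_name",
        ],
    )
    return layout.planted, truth


def _jitter_copy(
    t: TranscriptModel,
    transcript_id: str,
    gene_id: str,
    deltas: tuple[int, int],
) -> TranscriptModel:
    """Perturb only the outer coordinates of the terminal exons."""
    exons = list(t.exons)
    d_start, d_end = deltas
    first, last = exons[0], exons[-1]
    new_start = max(0, min(first.start + d_start, first.end - 20))
    new_end = max(last.start + 20, last.end + d_end)
    if len(exons) == 1:
        exons[0] = GenomeInterval(first.chrom, new_start, new_end, first.strand)
    else:
        exons[0] = GenomeInterval(first.chrom, new_start, first.end, first.strand)
        exons[-1] = GenomeInterval(last.chrom, last.start, new_end, last.strand)
    return TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id, exons=tuple(exons)
    )


def simulate_method_catalogs(
    reference: TranscriptCatalog,
    planted: Sequence[TranscriptModel],
    params: SimulationParams,
) -> tuple[list[MethodCatalog], np.ndarray]:
    """Three noisy per-method catalogs plus the K x 3 detection matrix."""
    layout = _build_layout(params)
    ref_txs = list(reference.transcripts())
    n_methods = len(params.method_labels)
    K = len(planted)

    rng_detect = params.rng(_S_DETECT)
    detected = rng_detect.random((K, n_methods)) < np.asarray(params.p_detect)
    rng_jitter = params.rng(_S_JITTER)
    j = params.end_jitter
    jit = (
        rng_jitter.integers(-j, j + 1, size=(K, n_methods, 2))
        if j > 0
        else np.zeros((K, n_methods, 2), dtype=int)
    )
    cont_jit = (
        rng_jitter.integers(-j, j + 1, size=(len(layout.contaminants), n_methods, 2))
        if j > 0
        else np.zeros((len(layout.contaminants), n_methods, 2), dtype=int)
    )

    n_mono = int(round(params.mono_exonic_rate * params.n_planted))
    n_short = int(round(params.short_transcript_rate * params.n_planted))
    n_known_re = int(round(params.known_reassembly_rate * params.n_planted))
    n_iso = int(round(params.novel_isoform_rate * params.n_planted))

    catalogs: list[MethodCatalog] = []
    for m, label in enumerate(params.method_labels):
        rng_art = params.rng(_S_ART, m)
        txs: list[TranscriptModel] = []
        for i, t in enumerate(planted):
            if detected[i, m]:
                txs.append(
                    _jitter_copy(t, f"{label}|{t.transcript_id}", t.gene_id, tuple(jit[i, m]))
                )
        for i, t in enumerate(layout.contaminants):
            txs.append(
                _jitter_copy(t, f"{label}|{t.transcript_id}", t.gene_id, tuple(cont_jit[i, m]))
            )
        art_slots = layout.slots
        for a in range(n_mono):
            slot = art_slots[int(rng_art.integers(0, len(art_slots)))]
            length = int(rng_art.integers(100, 1_001))
            start = slot.start + _ART_ZONE[0] + int(
                rng_art.integers(0, _ART_ZONE[1] - _ART_ZONE[0] - length)
            )
            txs.append(
                TranscriptModel(
                    transcript_id=f"{label}|MONO{a:03d}",
                    gene_id=f"{label}|MONOG{a:03d}",
                    exons=(GenomeInterval(slot.chrom, start, start + length, "."),),
                )
            )
        for a in range(n_short):
            slot = art_slots[int(rng_art.integers(0, len(art_slots)))]
            start = slot.start + _ART_ZONE[0] + int(rng_art.integers(0, 3_000))
            strand = "+" if rng_art.random() < 0.5 else "-"
            e1 = GenomeInterval(slot.chrom, start, start + 80, strand)
            e2 = GenomeInterval(slot.chrom, start + 200, start + 300, strand)
            txs.append(
                TranscriptModel(
                    transcript_id=f"{label}|SHORT{a:03d}",
                    gene_id=f"{label}|SHORTG{a:03d}",
                    exons=(e1, e2),  # mature length 180 <= 200
                )
            )
        for a in range(n_known_re):
            src = ref_txs[int(rng_art.integers(0, len(ref_txs)))]
            d = tuple(rng_art.integers(-j, j + 1, size=2)) if j > 0 else (0, 0)
            txs.append(
                _jitter_copy(src, f"{label}|KRE{a:03d}", f"{label}|KREG{a:03d}", d)
            )
        for a in range(n_iso):
            src = ref_txs[int(rng_art.integers(0, len(ref_txs)))]
            introns = [
                (x.end, y.start)
                for x, y in zip(src.exons, src.exons[1:])
                if y.start - x.end >= 300
            ]
            if not introns:
                continue
            istart, iend = introns[int(rng_art.integers(0, len(introns)))]
            extra = GenomeInterval(src.chrom, istart + 110, istart + 190, src.strand)
            txs.append(
                TranscriptModel(
                    transcript_id=f"{label}|ISO{a:03d}",
                    gene_id=f"{label}|ISOG{a:03d}",
                    exons=tuple(sorted(src.exons + (extra,), key=lambda e: e.start)),
                )
            )
        loci = cluster_loci(txs, stranded=True, gene_id_prefix=f"XLOC_{m + 1}")
        provenance = {t.transcript_id: frozenset({label}) for t in txs}
        catalogs.append(
            MethodCatalog(
                method_label=label,
                catalog=TranscriptCatalog(loci=tuple(loci), provenance=provenance),
            )
        )
    return catalogs, detected


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _motif_free_sequence(
    rng: np.random.Generator, length: int, matcher: MotifMatcher
) -> str:
    for _ in range(50):
        seq = _random_sequence(rng, length)
        if not any(matcher(p) for p in six_frame_translate(seq)):
            return seq
    raise SimulationError("could not draw a motif-free sequence")


def emit_scores_sequences_expression(
    planted: Sequence[TranscriptModel],
    catalogs: Sequence[MethodCatalog],
    params: SimulationParams,
) -> tuple[CodingScoreTable, dict[str, str], ExpressionMatrix]:
    """Coding scores, transcript sequences, and the FPKM matrix.

    Scores and sequences cover every per-method copy of the planted
    lincRNAs and the coding contaminants — exactly the transcripts that can
    reach the domain and coding-potential filters. Planted genes receive
    scores below the cutoff and motif-free sequences; contaminants receive
    scores strictly above 100 decibans and (every second one) the planted
    domain motif. FPKM rows are keyed by final gene names, with the first
    ``round(fraction_below_floor * K)`` planted genes deterministically
    placed below the floor in every population.
    """
    layout = _build_layout(params)
    matcher = MotifMatcher([DOMAIN_MOTIF])
    rng_scores = params.rng(_S_SCORES)
    K = len(planted)
    planted_scores = rng_scores.uniform(-200.0, 50.0, size=K)
    cont_scores = rng_scores.uniform(100.5, 400.0, size=len(layout.contaminants))

    scores: dict[str, float] = {}
    sequences: dict[str, str] = {}
    planted_by_tid = {t.transcript_id: i for i, t in enumerate(planted)}
    cont_by_tid = {t.transcript_id: i for i, t in enumerate(layout.contaminants)}
    for m, method in enumerate(catalogs):
        for t in method.catalog.transcripts():
            base_tid = t.transcript_id.split("|", 1)[-1]
            if base_tid in planted_by_tid:
                i = planted_by_tid[base_tid]
                scores[t.transcript_id] = float(planted_scores[i])
                rng = params.rng(_S_SEQ, 0, i, m)
                sequences[t.transcript_id] = _motif_free_sequence(
                    rng, transcript_length(t), matcher
                )
            elif base_tid in cont_by_tid:
                i = cont_by_tid[base_tid]
                scores[t.transcript_id] = float(cont_scores[i])
                rng = params.rng(_S_SEQ, 1, i, m)
                seq = _motif_free_sequence(rng, transcript_length(t), matcher)
                if i % 2 == 0:  # every second contaminant also carries the motif
                    pos = 30
                    seq = seq[:pos] + DOMAIN_MOTIF_NT + seq[pos + len(DOMAIN_MOTIF_NT):]
                sequences[t.transcript_id] = seq

    rng_expr = params.rng(_S_EXPR)
    populations = tuple(f"pop{p + 1:02d}" for p in range(params.n_populations))
    n_below = int(round(params.fraction_below_floor * K))
    genes: list[str] = []
    values: list[np.ndarray] = []
    for i, t in enumerate(planted):
        name = layout.expected_names[t.gene_id]
        genes.append(name)
        if i < n_below:
            row = rng_expr.uniform(0.0, 0.2, size=params.n_populations)
        else:
            row = rng_expr.uniform(0.0, 5.0, size=params.n_populations)
            row[int(rng_expr.integers(0, params.n_populations))] = rng_expr.uniform(
                0.25, 30.0
            )
        values.append(row)
    for t in list(layout.coding) + list(layout.known_lincs):
        genes.append(t.gene_id)
        values.append(rng_expr.uniform(0.5, 100.0, size=params.n_populations))
    matrix = ExpressionMatrix(
        genes=tuple(genes),
        populations=populations,
        values=np.array(values) if values else np.empty((0, params.n_populations)),
    )
    return CodingScoreTable(scores=scores), sequences, matrix


@dataclass
class SyntheticBundle:
    params: SimulationParams
    reference: TranscriptCatalog
    planted: list[TranscriptModel]
    method_catalogs: list[MethodCatalog]
    scores: CodingScoreTable
    sequences: dict[str, str]
    expression: ExpressionMatrix
    truth: pd.DataFrame = field(repr=False)


def generate_bundle(params: SimulationParams) -> SyntheticBundle:
    """Run the full simulation and assemble the completed truth table."""
    reference = generate_reference(params)
    planted, truth = plant_novel_lincs(reference, params)
    catalogs, detected = simulate_method_catalogs(reference, planted, params)
    scores, sequences, expression = emit_scores_sequences_expression(
        planted, catalogs, params
    )
    K = len(planted)
    n_below = int(round(params.fraction_below_floor * K))
    for m, label in enumerate(params.method_labels):
        truth[f"detected_{label}"] = detected[:, m]
    truth["n_methods_detected"] = detected.sum(axis=1)
    # same stream and order as emit_scores_sequences_expression
    truth["coding_score"] = params.rng(_S_SCORES).uniform(-200.0, 50.0, size=K)
    truth["below_floor"] = [i < n_below for i in range(K)]
    truth["max_fpkm"] = [
        expression.max_fpkm(truth.expected_name.iloc[i]) for i in range(K)
    ]
    truth["expected_survival"] = (truth["n_methods_detected"] >= 2) & (
        ~truth["below_floor"]
    )
    return SyntheticBundle(
        params=params,
        reference=reference,
        planted=planted,
        method_catalogs=catalogs,
        scores=scores,
        sequences=sequences,
        expression=expression,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the input bundle (GTFs, FASTA, TSVs, truth, config) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["reference"] = outdir / "reference.gtf"
    lio.write_gtf(bundle.reference, paths["reference"])
    for m, method in enumerate(bundle.method_catalogs, start=1):
        key = f"method_{m}"
        paths[key] = outdir / f"{key}.gtf"
        lio.write_gtf(method.catalog, paths[key])
    paths["fasta"] = outdir / "transcripts.fasta"
    lio.write_fasta(bundle.sequences, paths["fasta"])
    paths["scores"] = outdir / "scores.tsv"
    lio.write_coding_scores(bundle.scores, paths["scores"])
    paths["fpkm"] = outdir / "fpkm.tsv"
    lio.write_expression_table(bundle.expression, paths["fpkm"])
    paths["truth"] = outdir / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["motifs"] = outdir / "motifs.txt"
    paths["motifs"].write_text(DOMAIN_MOTIF + "\n")
    paths["config"] = outdir / "pipeline.cfg"
    lines = [
        f"reference_gtf = {paths['reference']}",
        f"fasta = {paths['fasta']}",
        f"scores_tsv = {paths['scores']}",
        f"fpkm_tsv = {paths['fpkm']}",
        f"motifs = {paths['motifs']}",
        f"out_dir = {outdir / 'pipeline_out'}",
    ]
    for m, method in enumerate(bundle.method_catalogs, start=1):
        lines.append(f"method.{method.method_label} = {outdir / f'method_{m}.gtf'}")
    paths["config"].write_text("\n".join(lines) + "\n")
    return paths


def recovery_counts(
    final_catalog: TranscriptCatalog, truth: pd.DataFrame
) -> tuple[int, int]:
    """(planted genes recovered, artifact genes leaked) in a final catalog."""
    expected = set(truth["expected_name"]) if len(truth) else set()
    final_genes = {locus.gene_id for locus in final_catalog.loci}
    recovered = len(final_genes & expected)
    artifacts = len(final_genes - expected)
    return recovered, artifacts
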