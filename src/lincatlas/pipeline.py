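"""End-to-end orchestration of the discovery pipeline.

Stage order, per reconstruction method: merge per-population catalogs,
drop non-intergenic transcripts, apply the structural filter, the domain
screen, and the coding-potential filter; then integrate the methods under
the 2-of-3 consensus rule, rename surviving genes after their nearest
protein-coding gene, and apply the expression floor.

The run is driven by a flat ``key = value`` config file; every threshold
defaults to the published value, so a config only needs file locations::

    reference_gtf = ref.gtf
    method.tophat_cufflinks = pop1.gtf,pop2.gtf
    method.star_cufflinks = sc.gtf
    method.star_trinity_pasa = stp.gtf
    scores_tsv = scores.tsv
    fasta = transcripts.fasta        # optional; omit to skip the domain screen
    motifs = motifs.txt              # motif list for the naive matcher
    fpkm_tsv = fpkm.tsv
    out_dir = out/

Every removed transcript is logged (stage, rule, id) at debug level, and the
report counts telescope: at every stage input − removed = output.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from . import io as lio
from .consensus import MethodCatalog, build_consensus, merge_populations, write_consensus_summary
from .expression import filter_expressed
from .filters import (
    MotifMatcher,
    filter_coding_potential,
    filter_domain_hits,
    filter_structural,
)
from .model import (
    LincAtlasError,
    PipelineConfig,
    PipelineError,
    TranscriptCatalog,
)
from .naming import NAME_RE, assign_names, coding_loci, write_name_mapping
from .novelty import filter_intergenic

logger = logging.getLogger(__name__)

_BOOL_KEYS = {
    "intergenic_stranded",
    "expression_inclusive",
    "strict_scores",
    "strict_expression",
}
_INT_KEYS = {"min_transcript_length", "min_exons", "min_methods", "n_methods"}
_FLOAT_KEYS = {"coding_score_cutoff", "expression_floor"}
_STR_KEYS = {"consensus_support"}


@dataclass
class RunSpec:
    """Parsed pipeline configuration: file locations plus thresholds."""

    reference_gtf: Path
    methods: dict[str, list[Path]]  # label -> per-population GTFs
    scores_tsv: Path
    fpkm_tsv: Path
    out_dir: Path
    fasta: Path | None = None
    motifs: Path | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)


def parse_config(path: str | Path) -> RunSpec:
    """Parse a flat key = value config file into a :class:`RunSpec`."""
    path = Path(path)
    raw: dict[str, str] = {}
    methods: dict[str, list[Path]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise PipelineError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("method."):
            label = key[len("method.") :]
            methods[label] = [Path(p.strip()) for p in value.split(",") if p.strip()]
        else:
            raw[key] = value
    for required in ("reference_gtf", "scores_tsv", "fpkm_tsv", "out_dir"):
        if required not in raw:
            raise PipelineError(f"{path}: missing required config key {required!r}")
    if len(methods) < 2:
        raise PipelineError(
            f"{path}: at least 2 method catalogs required, found {len(methods)}"
        )
    overrides = {}
    for key, value in raw.items():
        if key in _BOOL_KEYS:
            overrides[key] = value.lower() in ("1", "true", "yes", "on")
        elif key in _INT_KEYS:
            overrides[key] = int(value)
        elif key in _FLOAT_KEYS:
            overrides[key] = float(value)
        elif key in _STR_KEYS:
            overrides[key] = value
    overrides.setdefault("n_methods", max(len(methods), 2))
    config = PipelineConfig(**overrides)
    return RunSpec(
        reference_gtf=Path(raw["reference_gtf"]),
        methods=methods,
        scores_tsv=Path(raw["scores_tsv"]),
        fpkm_tsv=Path(raw["fpkm_tsv"]),
        out_dir=Path(raw["out_dir"]),
        fasta=Path(raw["fasta"]) if "fasta" in raw else None,
        motifs=Path(raw["motifs"]) if "motifs" in raw else None,
        config=config,
    )


@dataclass
class StageCount:
    stage: str
    scope: str  # method label, or "all" for integrated stages
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class PipelineReport:
    stages: list[StageCount] = field(default_factory=list)
    final_genes: int = 0
    final_transcripts: int = 0

    def add(self, stage: str, scope: str, n_in: int, n_out: int) -> None:
        self.stages.append(StageCount(stage, scope, n_in, n_in - n_out, n_out))

    def telescopes(self) -> bool:
        """Counts are consistent: in − removed = out, and stages chain."""
        by_scope: dict[str, list[StageCount]] = {}
        for s in self.stages:
            if s.n_in - s.n_removed != s.n_out:
                return False
            by_scope.setdefault(s.scope, []).append(s)
        for stages in by_scope.values():
            for a, b in zip(stages, stages[1:]):
                if a.n_out != b.n_in:
                    return False
        return True

    def to_dict(self) -> dict:
        return {
            "stages": [vars(s) for s in self.stages],
            "final_genes": self.final_genes,
            "final_transcripts": self.final_transcripts,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def run_pipeline(
    config_path: str | Path, write_intermediates: bool = True
) -> tuple[TranscriptCatalog, PipelineReport]:
    """Run the full discovery pipeline as configured; return (catalog, report)."""
    spec = parse_config(config_path)
    return run_pipeline_spec(spec, write_intermediates=write_intermediates)


def run_pipeline_spec(
    spec: RunSpec, write_intermediates: bool = True
) -> tuple[TranscriptCatalog, PipelineReport]:
    config = spec.config
    out = spec.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()

    def persist(catalog: TranscriptCatalog, name: str) -> None:
        if write_intermediates:
            lio.write_gtf(catalog, out / name)

    def stage(name: str, scope: str, before: int, catalog: TranscriptCatalog) -> int:
        report.add(name, scope, before, catalog.n_transcripts)
        persist(catalog, f"{scope}.{name}.gtf")
        return catalog.n_transcripts

    try:
        reference = lio.read_gtf(spec.reference_gtf)
        scores = lio.read_coding_scores(spec.scores_tsv)
        matrix = lio.read_expression_table(spec.fpkm_tsv)
        sequences = lio.read_fasta(spec.fasta) if spec.fasta else None
        matcher = (
            MotifMatcher.from_file(spec.motifs) if spec.motifs is not None else None
        )
    except LincAtlasError as exc:
        raise PipelineError(f"input loading failed: {exc}") from exc

    filtered_methods: list[MethodCatalog] = []
    for label in sorted(spec.methods):
        try:
            populations = [lio.read_gtf(p) for p in spec.methods[label]]
            method = merge_populations(populations, label)
            n = method.catalog.n_transcripts
            report.add(
                "merge_populations",
                label,
                sum(c.n_transcripts for c in populations),
                n,
            )
            persist(method.catalog, f"{label}.merge_populations.gtf")

            catalog = filter_intergenic(
                method.catalog,
                reference,
                config,
                log_path=(out / f"{label}.novelty.tsv") if write_intermediates else None,
            )
            n = stage("filter_intergenic", label, n, catalog)

            catalog = filter_structural(catalog, config)
            n = stage("filter_structural", label, n, catalog)

            if sequences is not None and matcher is not None:
                catalog = filter_domain_hits(
                    catalog,
                    sequences,
                    matcher,
                    log_path=(out / f"{label}.domain_hits.tsv")
                    if write_intermediates
                    else None,
                )
                n = stage("filter_domain_hits", label, n, catalog)

            catalog = filter_coding_potential(catalog, scores, config)
            n = stage("filter_coding_potential", label, n, catalog)
        except LincAtlasError as exc:
            raise PipelineError(f"stage failed for method {label!r}: {exc}") from exc
        filtered_methods.append(MethodCatalog(method_label=label, catalog=catalog))

    try:
        consensus = build_consensus(filtered_methods, config)
    except LincAtlasError as exc:
        raise PipelineError(f"consensus stage failed: {exc}") from exc
    report.add(
        "build_consensus",
        "all",
        sum(m.catalog.n_transcripts for m in filtered_methods),
        consensus.n_transcripts,
    )
    persist(consensus, "all.build_consensus.gtf")
    if write_intermediates:
        write_consensus_summary(consensus, out / "consensus_summary.tsv")

    try:
        named, records = (
            assign_names(consensus, coding_loci(reference))
            if consensus.loci
            else (consensus, [])
        )
    except LincAtlasError as exc:
        raise PipelineError(f"naming stage failed: {exc}") from exc
    report.add("assign_names", "all", consensus.n_transcripts, named.n_transcripts)
    if write_intermediates:
        write_name_mapping(records, out / "name_mapping.tsv")

    try:
        final = filter_expressed(named, matrix, config)
    except LincAtlasError as exc:
        raise PipelineError(f"expression stage failed: {exc}") from exc
    report.add("filter_expressed", "all", named.n_transcripts, final.n_transcripts)

    lio.write_gtf(final, out / "final_catalog.gtf")
    report.final_genes = final.n_genes
    report.final_transcripts = final.n_transcripts
    report.write(out / "report.json")
    if not report.telescopes():  # defensive: accounting must always close
        raise PipelineError("stage counts do not telescope")
    return final, report


def validate_catalog(path: str | Path, check_names: bool = False) -> list[str]:
    """Lint a GTF catalog; returns a list of human-readable violations."""
    path = Path(path)
    violations: list[str] = []
    try:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    violations.append(f"line {lineno}: {len(cols)} columns (need 9)")
                    continue
                try:
                    start, end = int(cols[3]), int(cols[4])
                    if end < start or start < 1:
                        violations.append(
                            f"line {lineno}: invalid coordinates {start}..{end}"
                        )
                except ValueError:
                    violations.append(f"line {lineno}: non-integer coordinates")
                if cols[6] not in ("+", "-", "."):
                    violations.append(f"line {lineno}: invalid strand {cols[6]!r}")
                if "transcript_id" not in cols[8] or "gene_id" not in cols[8]:
                    violations.append(f"line {lineno}: missing id attributes")
    except OSError as exc:
        return [f"unreadable: {exc}"]
    if violations:
        return violations
    try:
        catalog = lio.read_gtf(path)
    except LincAtlasError as exc:
        return [str(exc)]
    seen_names: set[str] = set()
    for locus in catalog.loci:
        for t in locus.transcripts:
            if t.n_exons >= 2 and t.strand == ".":
                violations.append(
                    f"transcript {t.transcript_id}: multi-exonic but unstranded"
                )
        if check_names:
            if not NAME_RE.match(locus.gene_id):
                violations.append(
                    f"gene {locus.gene_id}: does not match the naming grammar"
                )
            if locus.gene_id in seen_names:
                violations.append(f"gene {locus.gene_id}: duplicate name")
            seen_names.add(locus.gene_id)
    return violations


def looks_like_final_catalog(catalog: TranscriptCatalog) -> bool:
    return bool(catalog.loci) and all(
        re.match(r"^linc-", locus.gene_id) for locus in catalog.loci
    )
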