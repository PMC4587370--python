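"""Consensus merging of per-method catalogs with a 2-of-3 support rule.

Per reconstruction method, per-population catalogs are first merged into one
method-level catalog, collapsing chain-equal duplicates to a single
representative whose ends are the widest union of the duplicates' ends
(intron coordinates never change). The method-level catalogs are then
integrated: transcripts from all methods are clustered into cross-method
loci by same-strand exonic overlap, and only loci supported by at least
``min_methods`` distinct methods (default 2 of 3) survive. Surviving loci
collapse chain-equal transcripts across methods the same way, with merged
provenance, yielding a non-redundant atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .algebra import chain_key, cluster_loci
from .model import (
    GenomeInterval,
    ModelValidationError,
    PipelineConfig,
    TranscriptCatalog,
    TranscriptModel,
    empty_catalog,
)


@dataclass(frozen=True)
class MethodCatalog:
    """One reconstruction method's merged catalog, tagged with its label."""

    method_label: str
    catalog: TranscriptCatalog


def _widest_union(group: Sequence[TranscriptModel]) -> TranscriptModel:
    """Collapse chain-equal transcripts to one model with the widest ends.

    The representative keeps the lexicographically smallest transcript id and
    gene id of that member; first-exon start is the minimum and last-exon end
    the maximum over the group, introns are untouched.
    """
    rep = min(group, key=lambda t: t.transcript_id)
    start = min(t.start for t in group)
    end = max(t.end for t in group)
    exons = list(rep.exons)
    first, last = exons[0], exons[-1]
    if len(exons) == 1:
        exons[0] = GenomeInterval(first.chrom, start, end, first.strand)
    else:
        exons[0] = GenomeInterval(first.chrom, start, first.end, first.strand)
        exons[-1] = GenomeInterval(last.chrom, last.start, end, last.strand)
    attributes: dict[str, str] = {}
    for t in sorted(group, key=lambda t: t.transcript_id):
        attributes.update(t.attributes)
    return replace(rep, exons=tuple(exons), attributes=attributes)


def collapse_chain_duplicates(
    transcripts: Iterable[TranscriptModel],
    provenance: dict[str, frozenset[str]],
) -> tuple[list[TranscriptModel], dict[str, frozenset[str]]]:
    """Merge chain-equal transcripts; mono-exonic models are never merged."""
    groups: dict = {}
    order: list = []
    for t in transcripts:
        key = chain_key(t) or ("mono", t.transcript_id)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(t)
    merged: list[TranscriptModel] = []
    new_provenance: dict[str, frozenset[str]] = {}
    for key in order:
        group = groups[key]
        rep = _widest_union(group) if len(group) > 1 else group[0]
        merged.append(rep)
        support: frozenset[str] = frozenset()
        for t in group:
            support |= provenance.get(t.transcript_id, frozenset())
        new_provenance[rep.transcript_id] = support
    return merged, new_provenance


def merge_populations(
    per_population: Sequence[TranscriptCatalog], method_label: str
) -> MethodCatalog:
    """Merge one method's per-population catalogs into a method catalog.

    Chain-equal duplicates assembled in different populations collapse to the
    widest-end representative; loci are re-clustered (stranded); every
    transcript's provenance becomes ``{method_label}``.
    """
    if not per_population:
        raise ModelValidationError("merge_populations requires >= 1 catalog")
    seen: dict[str, TranscriptModel] = {}
    pooled: list[TranscriptModel] = []
    for catalog in per_population:
        for t in catalog.transcripts():
            if t.transcript_id in seen:
                if seen[t.transcript_id].exons != t.exons:
                    raise ModelValidationError(
                        f"transcript id {t.transcript_id!r} reused for a "
                        "different model across population catalogs"
                    )
                continue
            seen[t.transcript_id] = t
            pooled.append(t)
    merged, _ = collapse_chain_duplicates(pooled, {})
    loci = cluster_loci(merged, stranded=True)
    provenance = {
        t.transcript_id: frozenset({method_label})
        for locus in loci
        for t in locus.transcripts
    }
    return MethodCatalog(
        method_label=method_label,
        catalog=TranscriptCatalog(loci=tuple(loci), provenance=provenance),
    )


def locus_support(
    locus_transcripts: Sequence[TranscriptModel],
    provenance: dict[str, frozenset[str]],
    mode: str = "locus",
) -> frozenset[str]:
    """Methods supporting a locus.

    ``locus`` mode (default, Cuffcompare-style): the union of methods over
    all member transcripts. ``chain`` mode (stricter): only methods that
    independently reconstructed the *same* intron chain count, i.e. the
    best-supported chain-equal group decides.
    """
    if mode == "locus":
        support: frozenset[str] = frozenset()
        for t in locus_transcripts:
            support |= provenance.get(t.transcript_id, frozenset())
        return support
    by_chain: dict = {}
    for t in locus_transcripts:
        key = chain_key(t) or ("mono", t.transcript_id)
        by_chain[key] = by_chain.get(key, frozenset()) | provenance.get(
            t.transcript_id, frozenset()
        )
    return max(by_chain.values(), key=lambda s: (len(s), sorted(s)))


def build_consensus(
    methods: Sequence[MethodCatalog], config: PipelineConfig | None = None
) -> TranscriptCatalog:
    """Integrate method catalogs and keep loci with >= min_methods support."""
    config = config or PipelineConfig()
    labels = [m.method_label for m in methods]
    if len(set(labels)) != len(labels):
        raise ModelValidationError(f"duplicate method labels in {labels}")
    pooled: list[TranscriptModel] = []
    provenance: dict[str, frozenset[str]] = {}
    for method in methods:
        for t in method.catalog.transcripts():
            if t.transcript_id in provenance:
                raise ModelValidationError(
                    f"transcript id {t.transcript_id!r} appears in more than "
                    "one method catalog; per-method ids must be unique"
                )
            pooled.append(t)
            prov = method.catalog.transcript_provenance(t.transcript_id)
            provenance[t.transcript_id] = prov or frozenset({method.method_label})
    loci = cluster_loci(pooled, stranded=True)
    survivors: list[TranscriptModel] = []
    surviving_prov: dict[str, frozenset[str]] = {}
    for locus in loci:
        support = locus_support(
            locus.transcripts, provenance, mode=config.consensus_support
        )
        if len(support) < config.min_methods:
            continue
        merged, merged_prov = collapse_chain_duplicates(locus.transcripts, provenance)
        survivors.extend(merged)
        surviving_prov.update(merged_prov)
    if not survivors:
        return empty_catalog()
    final_loci = cluster_loci(survivors, stranded=True)
    return TranscriptCatalog(loci=tuple(final_loci), provenance=surviving_prov)


def write_consensus_summary(catalog: TranscriptCatalog, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for locus in catalog.loci:
        methods: frozenset[str] = frozenset()
        for t in locus.transcripts:
            methods |= catalog.transcript_provenance(t.transcript_id)
        span = locus.span
        rows.append(
            {
                "gene_id": locus.gene_id,
                "n_methods": len(methods),
                "methods": ",".join(sorted(methods)),
                "n_transcripts": len(locus.transcripts),
                "span": f"{span.chrom}:{span.start}-{span.end}({span.strand})",
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene_id", "n_methods", "methods", "n_transcripts", "span"],
    ).to_csv(path, sep="\t", index=False)
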