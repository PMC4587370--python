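"""Per-method merging and the cross-method 2-of-3 consensus rule."""

import itertools
import random

import pytest

from lincatlas.algebra import exonic_overlap_bp
from lincatlas.consensus import (
    MethodCatalog,
    build_consensus,
    merge_populations,
)
from lincatlas.model import ModelValidationError, PipelineConfig

from conftest import catalog_of, random_transcript, tx


def method(label, *transcripts):
    catalog = catalog_of(*transcripts)
    return MethodCatalog(
        method_label=label,
        catalog=catalog_of(
            *transcripts,
            provenance={t.transcript_id: frozenset({label}) for t in transcripts},
        ),
    )


def brute_surviving_loci(methods, min_methods):
    """Oracle: union-find same-strand overlap loci + method counting."""
    txs = []
    origin = {}
    for m in methods:
        for t in m.catalog.transcripts():
            origin[t.transcript_id] = m.method_label
            txs.append(t)
    parent = list(range(len(txs)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(txs)), 2):
        a, b = txs[i], txs[j]
        if a.strand == b.strand and exonic_overlap_bp(a, b) >= 1:
            parent[find(i)] = find(j)
    loci = {}
    for i in range(len(txs)):
        loci.setdefault(find(i), []).append(txs[i])
    survivors = []
    for members in loci.values():
        if len({origin[t.transcript_id] for t in members}) >= min_methods:
            survivors.append(frozenset(t.transcript_id for t in members))
    return frozenset(survivors)


class TestMergePopulations:
    def test_chain_equal_duplicates_get_widest_ends(self):
        pop1 = catalog_of(tx("a1", [(100, 200), (300, 400)]))
        pop2 = catalog_of(tx("a2", [(70, 200), (300, 430)]))
        merged = merge_populations([pop1, pop2], "m1").catalog
        (t,) = list(merged.transcripts())
        assert t.transcript_id == "a1"  # lexicographically smallest member
        assert [(e.start, e.end) for e in t.exons] == [(70, 200), (300, 430)]
        assert merged.transcript_provenance("a1") == frozenset({"m1"})

    def test_disjoint_populations_union(self):
        pop1 = catalog_of(tx("a", [(0, 300), (400, 600)]))
        pop2 = catalog_of(tx("b", [(5000, 5300), (5400, 5600)]))
        assert merge_populations([pop1, pop2], "m").catalog.n_transcripts == 2

    def test_single_population_identity_plus_provenance(self):
        pop = catalog_of(tx("a", [(0, 300), (400, 600)]))
        merged = merge_populations([pop], "m").catalog
        (t,) = list(merged.transcripts())
        assert [(e.start, e.end) for e in t.exons] == [(0, 300), (400, 600)]
        assert merged.transcript_provenance("a") == frozenset({"m"})


class TestBuildConsensus:
    def test_two_of_three_rule(self):
        shared1 = tx("m1_a", [(100, 300), (400, 600)])
        shared2 = tx("m2_a", [(120, 300), (400, 580)])  # overlaps shared1
        lone = tx("m3_x", [(9000, 9300), (9400, 9600)])
        atlas = build_consensus(
            [method("m1", shared1), method("m2", shared2), method("m3", lone)]
        )
        assert atlas.n_genes == 1
        ids = {t.transcript_id for t in atlas.transcripts()}
        assert "m3_x" not in ids

    def test_min_methods_one_keeps_every_locus(self):
        lone = tx("m3_x", [(9000, 9300), (9400, 9600)])
        other = tx("m1_y", [(0, 300), (350, 700)])
        atlas = build_consensus(
            [method("m3", lone), method("m1", other)],
            PipelineConfig(min_methods=1),
        )
        assert atlas.n_genes == 2

    def test_three_chain_equal_copies_collapse_with_full_provenance(self):
        copies = [
            tx("m1_a", [(100, 300), (400, 600)]),
            tx("m2_a", [(90, 300), (400, 640)]),
            tx("m3_a", [(110, 300), (400, 590)]),
        ]
        atlas = build_consensus(
            [method(f"m{i + 1}", t) for i, t in enumerate(copies)]
        )
        (t,) = list(atlas.transcripts())
        assert t.transcript_id == "m1_a"
        assert [(e.start, e.end) for e in t.exons] == [(90, 300), (400, 640)]
        assert atlas.transcript_provenance("m1_a") == frozenset({"m1", "m2", "m3"})

    def test_duplicate_method_label_rejected(self):
        with pytest.raises(ModelValidationError):
            build_consensus([method("m1"), method("m1")])

    def test_monotone_in_min_methods(self, rng):
        methods = [
            method(f"m{m}", *[random_transcript(rng, f"m{m}_t{i}", span=3_000)
                              for i in range(15)])
            for m in range(3)
        ]
        gene_sets = []
        for k in (1, 2, 3):
            atlas = build_consensus(methods, PipelineConfig(min_methods=k))
            gene_sets.append(
                frozenset(
                    frozenset(t.transcript_id for t in l.transcripts)
                    for l in atlas.loci
                )
            )
        # survivors at stricter thresholds nest inside looser ones, locus-wise
        assert gene_sets[2] <= gene_sets[1] <= gene_sets[0]

    def test_invariant_under_method_permutation(self, rng):
        methods = [
            method(f"m{m}", *[random_transcript(rng, f"m{m}_t{i}", span=3_000)
                              for i in range(12)])
            for m in range(3)
        ]
        baseline = build_consensus(methods)
        for perm in itertools.permutations(methods):
            assert build_consensus(list(perm)) == baseline

    def test_idempotent_as_single_method(self, rng):
        methods = [
            method(f"m{m}", *[random_transcript(rng, f"m{m}_t{i}", span=3_000)
                              for i in range(12)])
            for m in range(3)
        ]
        atlas = build_consensus(methods)
        again = build_consensus(
            [MethodCatalog(method_label="atlas", catalog=atlas)],
            PipelineConfig(min_methods=1),
        )
        assert [l.span for l in again.loci] == [l.span for l in atlas.loci]
        assert [
            [t.exons for t in l.transcripts] for l in again.loci
        ] == [[t.exons for t in l.transcripts] for l in atlas.loci]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            methods = [
                method(
                    f"m{m}",
                    *[
                        random_transcript(rng, f"m{m}_t{i}", span=2_000)
                        for i in range(rng.randint(0, 20))
                    ],
                )
                for m in range(3)
            ]
            atlas = build_consensus(methods)
            got_loci = set()
            for locus in atlas.loci:
                members = set()
                for t in locus.transcripts:
                    members.add(t.transcript_id)
                got_loci.add(frozenset(members))
            expected = brute_surviving_loci(methods, 2)
            # the atlas collapses chain-equal duplicates, so compare loci by
            # the surviving representative ids being a subset with same count
            assert len(got_loci) == len(expected)
            for got in got_loci:
                assert any(got <= exp for exp in expected)
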