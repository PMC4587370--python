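# Methods

## Scope and model

`lincatlas` builds a catalog of novel intergenic lncRNA genes from already
assembled transcript models. Read processing, alignment, and assembly are
deliberately outside the package: inputs are exon-line GTF catalogs, a
per-transcript coding-score table, optional transcript sequences (FASTA),
and a gene × population FPKM matrix. The package's contribution is the
filter cascade, the cross-method consensus, and the nomenclature — the
steps that turn raw assemblies into a reusable annotation.

Two identity notions drive everything:

* **Transcript identity = intron-chain equality.** Two multi-exonic
  transcripts on the same chromosome and strand are the same isoform iff
  their ordered intron interval lists are identical. Terminal-exon end
  coordinates are ignored because assemblers place them unreliably.
  Mono-exonic transcripts have no chain and are never chain-equal (they are
  removed by the structural filter in any case). No fuzz tolerance is
  applied to splice sites: off-by-one chains stay distinct, which keeps
  every merge auditable.
* **Gene identity = overlap connectivity.** A gene locus is a connected
  component of transcripts under same-strand exonic overlap of at least one
  base (single linkage). This mirrors Cuffcompare-style locus fusion; no
  minimum overlap fraction is imposed, and the threshold would be the first
  thing to revisit for denser genomes.

## Thresholds (defaults in `PipelineConfig`)

| parameter | default | meaning |
|---|---|---|
| `min_transcript_length` | 201 nt | mature (exon-sum) length must exceed 200 nt, strict |
| `min_exons` | 2 | mono-exonic models are assembly-noise candidates and are dropped |
| `coding_score_cutoff` | 100 decibans | exclude score > 100 strictly; exactly 100 is kept |
| `min_methods` / `n_methods` | 2 / 3 | a gene needs independent reconstruction by ≥ 2 methods |
| `expression_floor` | 0.21 FPKM | inclusive; ≥ 0.21 in ≥ 1 population keeps a gene |
| `intergenic_stranded` | false | exonic overlap with the reference on *either* strand disqualifies a candidate from "intergenic" |
| `consensus_support` | `locus` | count a method if any member transcript came from it; `chain` demands chain-equal reconstruction |

Decisions behind the less obvious rows:

* The 200-nt rule uses **mature length**, not genomic span — the lncRNA
  definition concerns transcript length, and the spanwise reading would let
  a 2×50-nt transcript with a long intron pass.
* The expression comparator is **inclusive** ("at least 0.21") with an
  exclusive mode available, since both readings of such floors circulate.
  The floor is applied at gene level (max over populations of the gene's
  FPKM row); FPKM computation itself is an upstream concern.
* "Intergenic" excludes antisense-exonic overlaps by default: a candidate
  overlapping an annotated exon on the opposite strand is genic, not
  intergenic. A same-strand-only policy is available
  (`intergenic_stranded = true`).
* Candidates nested in a reference gene's intron with zero *exonic* overlap
  count as intergenic: exon-level overlap is the comparison primitive.
* "Gene identified by ≥ 2 methods" is evaluated at **locus** level (the
  weaker, overlap-based reading); `consensus_support = chain` provides the
  stricter transcript-level reading.
* Ties in the nearest-gene search break to the lexicographically smallest
  gene name; distance is span-to-span gap (0 when spans overlap); the locus
  **midpoint** decides up/down so geometries straddling a flank resolve
  deterministically. The counter scope is the full (gene, position,
  concordance) stem, counted in (chromosome, start) order.
* Missing coding scores and missing FPKM rows are hard errors by default;
  lenient modes (assume non-coding / drop unmeasured) log every assumption.

## Domain screen

The six-frame translation uses the standard genetic code (stops as `*`,
ambiguous codons as `X`, trailing partial codons dropped). The domain
search itself is a deterministic predicate (`DomainMatcher`): peptide in,
hit flag out. The shipped `MotifMatcher` does literal substring matching
against a motif list, which is sufficient to exercise the discard rule;
a production deployment can wrap an external profile-HMM search behind the
same predicate. The structural, domain, and coding filters commute and are
idempotent, so their order is immaterial (both orders are tested).

## Synthetic data

The generator emulates the *structure* of a discovery study, not its scale:
a reference of 260 protein-coding genes (2–10 exons) and 20 known lincRNA
genes laid out over 4 chromosomes of 3 Mb, 200 planted novel multi-exonic
intergenic lincRNAs (> 200 nt mature length), three method catalogs with
independent per-gene detection at probability 0.8 per method, terminal-end
jitter up to 30 nt that never moves a splice site, 13 populations in the
FPKM table, and artifact classes at 0.1–0.2 × the planted count per method.
Each artifact class is built to die at exactly one filter (mono-exonic
fragments and ≤ 200-nt transcripts at the structural filter, chain-equal
reassemblies of reference transcripts as "known", extra-exon variants as
"novel isoform", and intergenic coding contaminants at the domain or
coding-potential filter), so any artifact in a final catalog indicts a
specific stage.

Placement uses one fixed-width intergenic slot after each coding gene, with
at most one occupant (planted lincRNA, known lincRNA, or contaminant) per
slot, positioned a few hundred nt from the gene on its left and several kb
from the gene on its right. Consequences that the tests rely on:

* every planted gene's nearest coding gene, orientation tags, and counter
  (always `_1`) are known at generation time, so the FPKM table and truth
  table can be keyed by final names regardless of which planted genes
  survive detection;
* with equal detection probability p per method, a planted gene survives
  the 2-of-3 rule with probability 3p²(1−p) + p³ independently of the
  others, giving the closed-form recovery expectation used in the
  acceptance check (K = 200, p = 0.8 → 179.2, binomial SD ≈ 4.3).

The generator does **not** emulate read-level noise, splice-graph
complexity, overlapping gene architecture, fuzzy splice sites, or realistic
expression distributions beyond the floor behavior. Passing the recovery
experiment therefore demonstrates that the pipeline's logic is correct
under its own identity definitions — not that those definitions are robust
to real assembler splice-site error, which would surface as under-merging
(duplicate loci), nor that detection is truly independent across methods on
real data.

All randomness flows from a single seed through named substreams (layout,
slot assignment, detection, jitter, scores, sequences, expression), so
changing one rate leaves unrelated draws untouched and regression tests
stay stable. The whole simulation is a pure function of its parameter set;
the same seed yields byte-identical bundle files.

## Problem sizes

The default test and acceptance workloads are desk-scale by design: oracle
comparisons use ≤ 60 transcripts per instance (where brute-force
enumeration is exact), and the recovery experiment uses 20 replicates of
200 planted genes (~4 000 Bernoulli survival trials), which bounds the
standard error of the mean at ~1 gene — ample to detect a broken filter or
consensus rule, each of which shifts the mean by tens of genes.

## Known limitations

* The consensus never meta-assembles partially overlapping chains into
  longer models (no Cuffmerge-style extension); duplicates are resolved
  only by exact chain equality.
* Unstranded transcripts survive parsing but cannot be named (no
  concordance tag is definable) — they are expected to die earlier as
  mono-exonic fragments, and naming an unstranded locus is a hard error.
* The nearest-gene search is restricted to the lincRNA's chromosome; a
  chromosome with no coding gene is a naming error rather than a guess.
* GTF I/O consumes exon features only; GFF3 and BAM/FASTQ are out of scope.
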