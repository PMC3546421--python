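# Methods

## Scope and data model

`tertkit` analyses three layers of TERT gene architecture: the exon/splice
structure of one gene, the domain–linker architecture of a protein family
alignment, and the chromosomal neighbourhood of the locus across two
genomes. Alignments are consumed, not built (any aligner's output in
aligned FASTA or CLUSTAL works), domain and motif boundaries are supplied
as curated annotations on a reference protein, and orthology is taken as
given in the input table. All internal coordinates are 0-based half-open;
GFF3 and the domain-map TSV keep their native 1-based inclusive
convention on disk. Gene models are processed in transcript orientation;
minus-strand input is reverse-complemented at load.

## Splice events and reading-frame classification

A splice event is normalised to an edit on the wild-type mature
transcript: a set of deleted transcript intervals and/or a cassette
inserted at an exon junction. Four kinds are supported — novel
donor→acceptor use (a genomic interval whose exonic part is removed),
whole-exon skipping, internal deletion in transcript coordinates, and
cassette insertion. All edits from a set of compatible events are applied
in one pass (deletions before insertions at equal coordinates, ties by
event id), and the resulting transcript carries per-segment provenance
that tiles its sequence exactly.

**Compatibility.** Two events are compatible when their *footprints* are
disjoint. A footprint is the closed transcript-coordinate interval from
the first to the last position an event deletes, inserts at, or splices
across — closed so that two events competing for the same splice junction
(e.g. a donor-truncation spliced to exon 3's acceptor versus a skip of
exon 3) intersect at the junction point. This derives the observed
mutual-exclusivity pattern among second-exon/exon-3 variants from
geometry rather than a hard-coded list. A consequence of the convention
is that adjacent-interval events (e.g. skips of neighbouring exons) are
also treated as exclusive, since they share a junction.

**Classification.** Codons are scanned from the image of the original
start codon in the variant transcript. Statuses:

* `RETAINED` — the first in-frame stop is the image of the original stop;
* `PTC` — an in-frame stop strictly upstream of that image;
* `START_LOST` — the start codon was deleted or broken (distinct from
  PTC, so events removing exon 1 are not misreported);
* `READTHROUGH` — translation passes the original stop's image without
  terminating there (frame lost with no upstream stop, or the stop codon
  itself destroyed). This fourth status is needed for closure over
  arbitrary events; none of the worked example's variants produce it.

`net_frame_shift` is (inserted − deleted) mod 3 counted over edits
upstream of the stop codon's first base — edits confined to the stop
codon or the UTRs cannot shift the reading frame relative to the stop, and
excluding them keeps the invariant "RETAINED ⇒ shift 0" exact (a deletion
nibbling the stop codon's third base can reform a stop in place and
genuinely retain the frame).

The 50-nt exon-junction rule for NMD sensitivity is available as an
optional annotation (`nmd_rule=50`) and off by default; PTC status itself
is purely positional.

## The packaged worked example

The repository constructs, at import time, a 16-exon gene model matching
the published architecture of the platypus TERT mRNA: 4522-nt transcript
= 2-nt 5′ UTR + 3891-nt ORF (start and stop included; 1296 aa) + 629-nt
3′ UTR, with seven events — A/A3 from a novel donor 72 nt into exon 2
(its first quarter), A2/A4 from a donor 202 nt in (its last third), each
spliced to the acceptor of intron 2 or 3; B skipping exon 3; C removing
exons 7–8 and 100 nt of exon 9; D inserting a 25-nt cassette taken from
intron 1 at the exon-1/2 junction. The intron sequences and exact novel
splice-site offsets were never published, so exon lengths
(90, 300, 250, 12×270, 642) and donor offsets were chosen once to satisfy
every stated property: A deletes 228 nt (≡0 mod 3, retained), A4 deletes
348 nt (retained), A2/A3/B/C/D shift the frame (exon 3's 250 nt ≡ 1
mod 3 makes A3 and B frame-breaking automatically). The construction
asserts all of these — including the absence of junction-created stops in
A and A4 — every time it is built; the base-level sequence comes from a
fixed seed.

## Alignment statistics

**Column filtering.** A column is removed when its fraction of gaps
(plus X, when `treat_x_as_gap`) exceeds the tolerance; tolerance 0
removes every column containing either. Filtering is idempotent and
monotone in the tolerance; kept 0-based indices are reported.

**Similarity.** A reference residue counts as similar when the target
holds, in the same column, a residue scoring ≥ `min_score` (default 1,
i.e. strictly positive) in the substitution matrix. Exact identity always
counts — including X against X — while X against any different residue
never does; this keeps self-similarity at exactly 100% without letting
unidentified residues inflate cross-species similarity. The denominator
is the number of reference residues in the region, so similarity is
deliberately asymmetric between sequences of unequal length. Percentages
are computed in exact rational arithmetic and rounded to one decimal only
for reporting. The matrix cutoff itself is a convention (the grouping
rules of classic alignment-shading tools are not published to the
residue); it is exposed as `min_score`.

**Regions and linkers.** A named region resolves to the alignment columns
from its first to its last reference residue, *including* interior
columns where the reference is gapped — insertions relative to the
reference stay inside their region. A linker's columns are those strictly
between the last reference residue of its upstream flank and the first of
its downstream flank (L1: TEN→TRBD; L2: v-II→v-III; L3: v-III→QFP), so a
species with a longer linker than the reference is still fully counted. A
species' linker length is its non-gap residue count in that band (X
counts as a residue). The cumulative statistic is
100·(l1+l2+l3)/(reference cumulative); classes are half-open intervals
[0, 60) SHORT, [60, 100) MEDIUM, [100, ∞) LONG, matching the prose
conventions "shorter than 60%", "60–99%", "100–160%"; 160% is treated as
an observed maximum that triggers a log notice, not a cap. Domain-map
boundaries ship as editable TSV data, since they come from manual
curation rather than an HMM.

**Distances and trees.** d(a,b) = 1 − (similar columns / jointly ungapped
columns), giving a symmetric matrix with zero diagonal (distance 1 when
no column is jointly ungapped). Neighbor joining is the classical
algorithm with ties in the Q criterion broken by the lexicographically
smallest taxon-name pair, making output deterministic; optional outgroup
rooting. This replaces — for grouping checks only — the Bayesian
inference used for publication-grade trees, which is out of scope.

## Synteny

Coverage over a segment counts genes by their reference start position
(membership of partially overlapping genes is by start, a stated
convention). Blocks: for each target chromosome, its mapped genes in
reference order form a run as long as no two consecutive members are
separated by more than `max_gap` interior genes (unmapped or assigned
elsewhere); runs shorter than `min_block_size` are dropped. Defaults
`min_block_size=3`, `max_gap=1` are this package's own convention — the
comparative literature describes shared synteny qualitatively — and both
are exposed in the API and CLI. This per-chromosome maximal-run
definition makes block membership monotone in `max_gap` and partitions
each chromosome's mapped genes at `max_gap=0`. Genes with an ortholog but
no chromosome assignment count toward coverage, never toward blocks.

The packaged segment fixture reproduces the published tallies of the
TERT-containing segment (70 genes, 61 with orthologs; 46 on X3, 7 on X2,
1 relocated to X1, 7 orthologs unplaced): it is synthetic, built from the
printed counts, because the gene-by-gene supplementary table is not
redistributed. The printed "90% mapped" is treated as a rounding of the
itemised counts (54/61 ≈ 88.5%).

## Synthetic-data generators

All generators draw from `numpy.random.default_rng([stream_offset, seed])`
with fixed per-operation offsets, so each is a pure function of its
parameters and seed, independent of call order; identical seeds give
byte-identical emitted files.

* **Families** use a star phylogeny: one ancestor per conserved block
  (TEN; TRBD split 40%/10%/50% around motif v-III; RT; CT), per-site
  substitution at `domain_sub_rate` (default 0.1 — high enough to spread
  similarity percentages, low enough to keep domains recognisably
  conserved), linkers drawn independently per species at their planted
  lengths. The true alignment places conserved blocks columnwise and
  left-justifies linkers in bands as wide as the family's longest linker.
  Default reference linkers (150, 100, 50) give a 300-residue cumulative
  reference, in the range seen for long-linker vertebrate TERTs. What the
  generator does *not* emulate: indels inside domains, rate variation
  across sites, or tree-structured descent — so passing recovery tests
  demonstrates the statistics' bookkeeping is exact on clean data, not
  robustness to alignment error.
* **Gene models** build the transcript first (UTR5 + ATG + sense codons +
  TAA + UTR3; the body is stop-free by construction), then cut it into
  exons of roughly the requested lengths with GT..AG introns. Defaults
  (2-nt 5′ UTR, 629-nt 3′ UTR) mirror the worked example's architecture.
* **Splice events** for a requested outcome are constructed (codon-aligned
  stop-free deletion for RETAINED; frame-shifting deletion or a cassette
  carrying a stop in every reading phase for PTC; start-covering deletion
  for START_LOST) and verified before emission by a direct string-splice
  plus Biopython translation — a code path separate from the classifier,
  so generator-vs-classifier agreement tests remain a two-route check.
* **Ortholog tables** lay planted runs consecutively from the segment
  start (adjacent runs must differ in chromosome, or they would merge);
  remaining genes alternate between two filler chromosomes so they can
  never form blocks. Noise: `unmapped_rate` drops the chromosome
  assignment, `relocation_rate` reassigns to a random other chromosome.

## Numerical and degenerate-input choices

Percentages use exact `Fraction` arithmetic before a single final
rounding; classification always uses the unrounded value. Empty filtered
alignments are legal output. A species with fully gapped linkers gets
length 0 (logged) and class SHORT. An all-gap similarity target scores
0%. `coverage_summary` of an empty segment reports zeros with an explicit
`fraction_mapped_defined=False` flag rather than dividing by zero. NJ
keeps negative branch lengths when the matrix is non-additive rather than
silently clamping.

## Known limitations

* Only '+'-strand (or whole-model reverse-complemented) gene models; no
  multi-isoform GFF3.
* The footprint-overlap compatibility rule is conservative for
  adjacent-exon skips (see above).
* Linker extraction assumes the domain map's reference is present and
  correctly aligned; misannotated boundaries propagate directly into the
  statistic.
* The similarity cutoff reproduces a score>0 convention; tools with
  bespoke residue groups may differ for rare residues (B, Z).
* Problem sizes in the test suite (families of ≤6 species, ~1000-residue
  proteins, ~1000 random splice events, 50–80-gene ortholog tables) were
  chosen as comfortably representative of the study-scale inputs while
  keeping the suite fast.
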