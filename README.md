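# tertkit

Comparative analysis of telomerase reverse transcriptase (TERT) gene
architecture, built for molecular-evolution work on vertebrate TERT genes
such as the platypus (*Ornithorhynchus anatinus*) TERT locus. The package
covers three analyses that recur in that kind of study, plus a
synthetic-data generator so every stage is testable without downloads:

1. **Alternative-splicing / reading-frame classification.** A gene model
   (GFF3 + genome FASTA) plus splice events — novel donor→acceptor use,
   exon skipping, internal deletion, cassette insertion — yields mature
   transcripts. Each variant is classified by scanning codons from the
   image of the original start codon: it is **ORF-retaining** when
   translation still terminates at the image of the original stop, i.e.
   the net coding-length change Δ = (inserted − deleted) satisfies
   Δ ≡ 0 (mod 3) and no new in-frame stop appears; otherwise it carries a
   **premature termination codon** (PTC), the hallmark of a
   nonsense-mediated-decay target. Start-codon loss and stop readthrough
   are reported as their own statuses.

2. **Domain-anchored alignment statistics.** Over a protein multiple
   alignment with reference-anchored domain/motif boundaries (TEN, TRBD,
   RT, CT domains; motifs such as v-II, v-III, QFP):
   gap-tolerance column filtering (at 0% tolerance every column holding a
   gap or an X is removed); reference-relative similarity,
   `percent = 100 · |{i : s(ref_i, tgt_i) > 0}| / |ref residues in region|`
   under BLOSUM62 (the TRBD figure excludes its internal linkers);
   per-species linker lengths L1 (TEN→TRBD), L2 (v-II→v-III),
   L3 (v-III→QFP) and the cumulative linker statistic
   `100 · (L1+L2+L3)_species / (L1+L2+L3)_reference`, classified
   LONG (≥100%), MEDIUM (60–99%) or SHORT (<60%); and
   similarity-derived distances with deterministic neighbor joining.

3. **Shared-synteny analysis.** From a table of reference genes in
   chromosome order and their ortholog assignments in a target genome:
   orthology coverage of a segment, ortholog counts per target
   chromosome, and synteny blocks — maximal runs of consecutive reference
   genes whose orthologs share a target chromosome, tolerating `max_gap`
   interrupting genes.

The generators in `tertkit.simulate` emit families with planted linker
lengths, multi-exon gene models with intact ORFs, splice events with
guaranteed frame outcomes, and ortholog tables with planted blocks — each
a pure function of (parameters, seed), with the planted truth serialised
alongside.

## Worked example

```sh
python examples/01_splice_variants.py
```

builds the packaged 16-exon worked example — a TERT-like gene with a
4522-nt transcript (2-nt 5′ UTR + 3891-nt ORF + 629-nt 3′ UTR) and its
seven described splice variants — and prints:

```
wild type: 4522 nt transcript, 1296 aa protein

variant  status     frame  length (nt)  protein (aa)
A        RETAINED       0         4294          1220
A2       PTC            1         4424           142
A3       PTC            2         4044            59
A4       RETAINED       0         4174          1180
B        PTC            2         4272           135
C        PTC            2         3882           524
D        PTC            1         4547            30
```

The 3891-nt ORF (start and stop codons included) encodes 1296 amino
acids. Variants A and A4 remove an in-frame, stop-free stretch of exon 2
(A also truncates into exon 3's acceptor) and keep the full downstream
frame; the other five shift the frame or introduce a stop, truncating the
protein at the listed lengths. The script then prints the pairwise
compatibility table: the five second-exon/exon-3 variants are mutually
exclusive (they compete for the same splice junctions) while each
combines with C or D.

The other examples (`examples/02`–`05`) walk through linker profiles,
column filtering + domain similarity, synteny blocks, and NJ trees the
same way. A thin CLI wraps the same functions, e.g.

```sh
tertkit --seed 7 --out-dir run1 simulate family
tertkit --out-dir run1 linkers --alignment run1/family.aln.fasta \
        --domains run1/family.domains.tsv
```

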