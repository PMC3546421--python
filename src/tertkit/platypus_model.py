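"""A reproducible platypus-TERT-like worked example.

The platypus TERT mRNA is 4522 nt: a 2-nt 5' UTR, a 3891-nt open reading
frame (start and stop codons included, encoding 1296 amino acids) and a
629-nt 3' UTR, transcribed from 16 exons. Seven alternative-splicing events
are described for it:

* A / A3 — a novel splice donor in the first quarter of exon 2, spliced to
  the acceptor of intron 2 (A) or intron 3 (A3);
* A2 / A4 — a novel donor in the last third of exon 2, spliced to the
  acceptor of intron 2 (A2) or intron 3 (A4);
* B — skip of exon 3;
* C — deletion of exons 7, 8 and part of exon 9;
* D — insertion of a 25-nt cassette derived from intron 1 at the
  exon-1/exon-2 junction.

A and A4 retain the reading frame; A2, A3, B, C and D introduce premature
termination codons. A..A4 and B are mutually exclusive (they compete for
the exon-2/exon-3 junctions) but each combines with C or D.

The intron sequences and exact novel splice-site offsets were never
published, so this module *constructs* a synthetic gene model with the same
architecture: exon count, transcript/ORF/UTR lengths, donor positions in
the stated quarters of exon 2, cassette length and every frame outcome are
reproduced, and all of them are asserted each time the fixture is built.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .core import EventKind, GeneModel, OrfStatus, SpliceEvent, STOP_CODONS
from .splicing import classify_orf, derive_transcript

# architecture constants of the worked example (see module docstring)
N_EXONS = 16
UTR5_LEN = 2
ORF_LEN = 3891  # incl. start and stop codons -> 1296 aa
UTR3_LEN = 629
TRANSCRIPT_LEN = UTR5_LEN + ORF_LEN + UTR3_LEN  # 4522
CASSETTE_LEN = 25

# exon lengths summing to 4522: exon 2 and 3 sized so that the four
# second-exon donor/acceptor combinations have the published frame outcomes
EXON_LENGTHS = (90, 300, 250) + (270,) * 12 + (642,)
DONOR_A = 72  # offset of the A/A3 novel donor within exon 2 (first quarter)
DONOR_A2 = 202  # offset of the A2/A4 novel donor within exon 2 (last third)
C_INTO_EXON9 = 100  # nt of exon 9 removed by variant C
INTRON_LEN = 200

# RNG seed for the synthetic intron/CDS bases; chosen once so that the
# build-time assertions below hold (no junction-created stop in A or A4,
# premature stops reachable in all shifted frames)
FIXTURE_SEED = 0

EXPECTED_STATUS = {
    "A": OrfStatus.RETAINED,
    "A2": OrfStatus.PTC,
    "A3": OrfStatus.PTC,
    "A4": OrfStatus.RETAINED,
    "B": OrfStatus.PTC,
    "C": OrfStatus.PTC,
    "D": OrfStatus.PTC,
}

# approximate domain layout of the 1296-aa product, residue coordinates
PROTEIN_DOMAINS = {
    "TEN": (0, 180),
    "TRBD": (350, 760),
    "RT": (760, 1100),
    "CT": (1100, 1296),
}

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def _random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _stop_free_cds(rng, orf_nt: int) -> str:
    """ATG + sense codons + TAA, no in-frame stop before the terminal one."""
    n_codons = orf_nt // 3
    body = "".join(
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
    )
    return "ATG" + body + "TAA"


def build_platypus_fixture() -> Tuple[GeneModel, Dict[str, SpliceEvent]]:
    """Construct the 16-exon gene model and its seven splice events.

    Deterministic; every published structural and frame property is
    asserted before returning.
    """
    assert sum(EXON_LENGTHS) == TRANSCRIPT_LEN
    rng = np.random.default_rng(FIXTURE_SEED)

    transcript = (
        _random_dna(rng, UTR5_LEN)
        + _stop_free_cds(rng, ORF_LEN)
        + _random_dna(rng, UTR3_LEN)
    )
    introns = ["GT" + _random_dna(rng, INTRON_LEN - 4) + "AG" for _ in range(N_EXONS - 1)]

    # assemble the genomic sequence and exon intervals
    exons, genome, t = [], [], 0
    gpos = 0
    for k, elen in enumerate(EXON_LENGTHS):
        genome.append(transcript[t : t + elen])
        exons.append((gpos, gpos + elen))
        gpos += elen
        t += elen
        if k < N_EXONS - 1:
            genome.append(introns[k])
            gpos += INTRON_LEN
    model = GeneModel(
        gene_id="OanTERT_like",
        sequence="".join(genome),
        exons=exons,
        cds_start=UTR5_LEN,
        cds_end=UTR5_LEN + ORF_LEN,
    )

    # genomic anchors for the donor/acceptor events
    e2_start = exons[1][0]
    e3_end_g = exons[2][1]
    donor_a_g = e2_start + DONOR_A
    donor_a2_g = e2_start + DONOR_A2
    acceptor_i2_g = exons[2][0]  # acceptor of intron 2 = start of exon 3
    acceptor_i3_g = exons[3][0]  # acceptor of intron 3 = start of exon 4
    e7_start_g = exons[6][0]
    c_acceptor_g = exons[8][0] + C_INTO_EXON9
    cassette = model.sequence[exons[0][1] : exons[0][1] + CASSETTE_LEN]  # from intron 1

    events = {
        "A": SpliceEvent("A", EventKind.ALT_DONOR_TO_ACCEPTOR, donor_a_g, acceptor_i2_g),
        "A2": SpliceEvent("A2", EventKind.ALT_DONOR_TO_ACCEPTOR, donor_a2_g, acceptor_i2_g),
        "A3": SpliceEvent("A3", EventKind.ALT_DONOR_TO_ACCEPTOR, donor_a_g, acceptor_i3_g),
        "A4": SpliceEvent("A4", EventKind.ALT_DONOR_TO_ACCEPTOR, donor_a2_g, acceptor_i3_g),
        "B": SpliceEvent("B", EventKind.EXON_SKIP, exons=(3,)),
        "C": SpliceEvent("C", EventKind.ALT_DONOR_TO_ACCEPTOR, e7_start_g, c_acceptor_g),
        "D": SpliceEvent(
            "D",
            EventKind.CASSETTE_INSERTION,
            start=EXON_LENGTHS[0],
            inserted_sequence=cassette,
        ),
    }

    _assert_fixture_properties(model, events)
    return model, events


def _assert_fixture_properties(model: GeneModel, events: Dict[str, SpliceEvent]) -> None:
    wt = derive_transcript(model, [])
    assert wt.length == TRANSCRIPT_LEN
    wt_call = classify_orf(model, wt)
    assert wt_call.status is OrfStatus.RETAINED
    assert wt_call.protein_length == (ORF_LEN // 3) - 1  # 1296 aa

    # donor placement: first quarter / last third of exon 2
    e2 = EXON_LENGTHS[1]
    assert 0 < DONOR_A <= e2 / 4
    assert DONOR_A2 >= 2 * e2 / 3
    assert len(events["D"].inserted_sequence) == CASSETTE_LEN

    for name, expect in EXPECTED_STATUS.items():
        tr = derive_transcript(model, [events[name]])
        call = classify_orf(model, tr)
        assert call.status is expect, (
            f"fixture variant {name}: expected {expect}, got {call.status}"
        )
    # D adds exactly the cassette
    tr_d = derive_transcript(model, [events["D"]])
    assert tr_d.length == TRANSCRIPT_LEN + CASSETTE_LEN
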