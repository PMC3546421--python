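"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, each a pure function of (parameters, seed):

* :func:`simulate_tert_family` — a star-phylogeny protein family with the
  TERT domain architecture: four conserved domains (TEN, TRBD, RT, CT)
  evolving by per-site substitution, separated by independently drawn
  variable-length linkers (L1 between TEN and TRBD; L2 and L3 inside the
  TRBD around motif v-III). Emits unaligned sequences, the true alignment
  (domains columnwise, linkers left-justified and gap-padded), the
  reference domain map and the planted truth.
* :func:`simulate_gene_model` — a multi-exon gene with an intact ORF
  (ATG start, stop-free body, terminal stop) split across exons with
  GT..AG introns.
* :func:`simulate_splice_events` — events engineered to a requested frame
  outcome (RETAINED / PTC / START_LOST), each verified before emission by
  a direct string-splice translation independent of the classifier.
* :func:`simulate_ortholog_table` — reference genes in order with planted
  target-chromosome runs plus unmapped/relocation noise.

Per-operation random substreams are derived from the seed by fixed
offsets, so generators stay independent of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core import (
    Alignment,
    DomainMap,
    EventKind,
    GeneModel,
    OrthologTable,
    SequenceRecord,
    SpliceEvent,
    STOP_CODONS,
    ValidationError,
)

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
DNA4 = np.array(list("ACGT"))
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# fixed substream offsets (design: one seedable source, offset-derived streams)
_STREAM_FAMILY, _STREAM_GENE, _STREAM_EVENTS, _STREAM_ORTHO = 11, 23, 37, 53


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(seed)])


def _random_protein(rng, n: int) -> str:
    return "".join(AA20[rng.integers(0, 20, size=n)]) if n else ""


def _random_dna(rng, n: int) -> str:
    return "".join(DNA4[rng.integers(0, 4, size=n)]) if n else ""


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [a for a in AA20 if a != chars[i]]
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------


@dataclass
class FamilyProfile:
    """Parameters of a simulated TERT-like protein family.

    ``linker_lengths`` holds one (l1, l2, l3) tuple per species; the first
    species is the reference (its linkers define 100%).
    """

    n_species: int
    domain_lengths: Dict[str, int] = field(
        default_factory=lambda: {"TEN": 160, "TRBD": 240, "RT": 300, "CT": 140}
    )
    linker_lengths: Optional[List[Tuple[int, int, int]]] = None
    domain_sub_rate: float = 0.1
    linker_sub_rate: float = 0.5  # linkers are drawn fresh; kept for the record
    seed: int = 0
    species_ids: Optional[List[str]] = None

    def __post_init__(self):
        if self.n_species < 1:
            raise ValidationError("need at least one species")
        for r in (self.domain_sub_rate, self.linker_sub_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"substitution rate {r} outside [0,1]")
        if self.linker_lengths is None:
            self.linker_lengths = [(150, 100, 50)] * self.n_species
        if len(self.linker_lengths) != self.n_species:
            raise ValidationError("one (l1,l2,l3) tuple per species required")
        for ls in self.linker_lengths:
            if any(l < 0 for l in ls):
                raise ValidationError("linker lengths must be >= 0")
        if self.species_ids is None:
            self.species_ids = ["ref"] + [
                f"sp{i:02d}" for i in range(2, self.n_species + 1)
            ]
        if len(self.species_ids) != self.n_species:
            raise ValidationError("one species id per species required")


@dataclass
class FamilyData:
    sequences: List[SequenceRecord]
    alignment: Alignment
    domain_map: DomainMap
    truth: dict


def simulate_tert_family(profile: FamilyProfile) -> FamilyData:
    """Generate a TERT-like family with planted domain/linker architecture."""
    rng = _rng(profile.seed, _STREAM_FAMILY)
    dl = profile.domain_lengths
    for d in ("TEN", "TRBD", "RT", "CT"):
        if d not in dl or dl[d] < 24:
            raise ValidationError(f"domain {d} missing or too short (min 24 aa)")

    # TRBD conserved part is split around motif v-III: [..v-II] v-III [QFP..]
    trbd_a = max(8, int(round(dl["TRBD"] * 0.4)))
    v3 = max(5, int(round(dl["TRBD"] * 0.1)))
    trbd_b = dl["TRBD"] - trbd_a - v3
    block_lens = [dl["TEN"], trbd_a, v3, trbd_b, dl["RT"], dl["CT"]]
    ancestor = [_random_protein(rng, n) for n in block_lens]

    species_blocks = []  # per species: list of 6 conserved blocks
    species_linkers = []  # per species: (l1seq, l2seq, l3seq)
    for s in range(profile.n_species):
        blocks = [_mutate(rng, b, profile.domain_sub_rate) for b in ancestor]
        l1, l2, l3 = profile.linker_lengths[s]
        linkers = (
            _random_protein(rng, l1),
            _random_protein(rng, l2),
            _random_protein(rng, l3),
        )
        species_blocks.append(blocks)
        species_linkers.append(linkers)

    # unaligned sequences: TEN L1 TRBDa L2 v-III L3 TRBDb RT CT
    def assemble(blocks, linkers):
        return (
            blocks[0] + linkers[0] + blocks[1] + linkers[1] + blocks[2]
            + linkers[2] + blocks[3] + blocks[4] + blocks[5]
        )

    seqs = [
        SequenceRecord(profile.species_ids[s], "synthetic TERT-like protein",
                       assemble(species_blocks[s], species_linkers[s]))
        for s in range(profile.n_species)
    ]

    # true alignment: conserved blocks columnwise, linker bands padded
    band = [max(ls[k] for ls in profile.linker_lengths) for k in range(3)]
    rows = {}
    for s in range(profile.n_species):
        b = species_blocks[s]
        l = species_linkers[s]
        rows[profile.species_ids[s]] = (
            b[0]
            + l[0].ljust(band[0], "-")
            + b[1]
            + l[1].ljust(band[1], "-")
            + b[2]
            + l[2].ljust(band[2], "-")
            + b[3] + b[4] + b[5]
        )
    alignment = Alignment(list(profile.species_ids), rows)

    # reference-coordinate domain map
    rl1, rl2, rl3 = profile.linker_lengths[0]
    p = 0
    regions = {}
    regions["GQ"] = (0, 8)
    regions["TEN"] = (p, p + dl["TEN"]); p += dl["TEN"]
    regions["L1"] = (p, p + rl1); p += rl1
    trbd_start = p
    p += trbd_a
    regions["v-II"] = (p - 8, p)
    regions["L2"] = (p, p + rl2); p += rl2
    regions["v-III"] = (p, p + v3); p += v3
    regions["L3"] = (p, p + rl3); p += rl3
    regions["QFP"] = (p, p + 8)
    p += trbd_b
    regions["TRBD"] = (trbd_start, p)
    regions["RT"] = (p, p + dl["RT"]); p += dl["RT"]
    regions["CT"] = (p, p + dl["CT"]); p += dl["CT"]
    domain_map = DomainMap(
        reference_id=profile.species_ids[0], regions=regions, reference_length=p
    )

    ref_cum = rl1 + rl2 + rl3
    truth = {
        "species": profile.species_ids,
        "linker_lengths": [list(t) for t in profile.linker_lengths],
        "cumulative": [sum(t) for t in profile.linker_lengths],
        "percent_of_reference": [
            100.0 * sum(t) / ref_cum if ref_cum else 0.0
            for t in profile.linker_lengths
        ],
        "reference_id": profile.species_ids[0],
        "band_widths": band,
        "domain_lengths": dict(dl),
        "seed": profile.seed,
    }
    return FamilyData(seqs, alignment, domain_map, truth)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def simulate_gene_model(
    n_exons: int,
    exon_length_range: Tuple[int, int] = (60, 400),
    seed: int = 0,
    orf_nt: Optional[int] = None,
    utr5: int = 2,
    utr3: int = 629,
    intron_length_range: Tuple[int, int] = (80, 300),
) -> GeneModel:
    """A random multi-exon gene model with an intact, stop-free ORF.

    ``orf_nt`` (including start and stop codons) defaults to a random
    multiple of 3 sized so exons land in ``exon_length_range`` on average.
    """
    if n_exons < 1:
        raise ValidationError("n_exons must be >= 1")
    rng = _rng(seed, _STREAM_GENE)
    lo, hi = exon_length_range
    if orf_nt is None:
        target_total = int(rng.integers(lo, hi + 1, size=n_exons).sum())
        orf_nt = max(9, ((target_total - utr5 - utr3) // 3) * 3)
    if orf_nt % 3 != 0 or orf_nt < 9:
        raise ValidationError("orf_nt must be a multiple of 3, at least 9")
    total = utr5 + orf_nt + utr3

    body = "".join(
        SENSE_CODONS[i]
        for i in rng.integers(0, len(SENSE_CODONS), size=orf_nt // 3 - 2)
    )
    transcript = _random_dna(rng, utr5) + "ATG" + body + "TAA" + _random_dna(rng, utr3)
    assert len(transcript) == total

    # partition the transcript into n_exons pieces, each >= 8 nt
    if n_exons == 1:
        lengths = [total]
    else:
        draws = rng.integers(lo, hi + 1, size=n_exons).astype(float)
        lengths = np.maximum(8, np.round(draws * total / draws.sum()).astype(int))
        diff = total - int(lengths.sum())
        lengths[-1] += diff
        if lengths[-1] < 8:  # re-balance pathological rounding
            need = 8 - int(lengths[-1])
            lengths[int(np.argmax(lengths[:-1]))] -= need
            lengths[-1] += need
        lengths = [int(x) for x in lengths]
    assert sum(lengths) == total

    ilo, ihi = intron_length_range
    introns = [
        "GT" + _random_dna(rng, int(rng.integers(ilo, ihi + 1)) - 4) + "AG"
        for _ in range(n_exons - 1)
    ]
    genome, exons, gpos, t = [], [], 0, 0
    for k, elen in enumerate(lengths):
        genome.append(transcript[t : t + elen])
        exons.append((gpos, gpos + elen))
        gpos += elen
        t += elen
        if k < n_exons - 1:
            genome.append(introns[k])
            gpos += len(introns[k])
    return GeneModel(
        gene_id=f"synthgene_seed{seed}",
        sequence="".join(genome),
        exons=exons,
        cds_start=utr5,
        cds_end=utr5 + orf_nt,
    )


# ---------------------------------------------------------------------------
# Splice events with guaranteed outcomes
# ---------------------------------------------------------------------------

# cassette with a stop codon reachable in every reading phase
_ALL_FRAME_STOP = "TTAATTAATTAA"


def _direct_outcome(model: GeneModel, event: SpliceEvent) -> str:
    """Frame outcome by direct string surgery + Biopython translation.

    Independent of the classifier: applies the single event to the spliced
    sequence with plain slicing, finds the start image by counting, and
    translates with Bio.Seq.
    """
    from .splicing import _event_edits  # normalisation only, no classification

    wt = model.spliced_sequence()
    dels, ins = _event_edits(model, event)
    cds_start, cds_end = model.cds_start, model.cds_end

    edited = wt
    shift_map_points = sorted(
        [(s, e, "") for s, e in dels] + [(p, p, seq) for p, seq in ins],
        reverse=True,
    )
    for s, e, seq in shift_map_points:
        edited = edited[:s] + seq + edited[e:]

    for s, e in dels:
        if s <= cds_start < e:
            return "START_LOST"
    start_img = cds_start
    for s, e, seq in [(s, e, "") for s, e in dels] + [(p, p, sq) for p, sq in ins]:
        if e <= cds_start or (seq and s <= cds_start):
            start_img += len(seq) - (e - s)
    if edited[start_img : start_img + 3] != "ATG":
        return "START_LOST"

    tail = edited[start_img:]
    prot = str(Seq(tail[: len(tail) - len(tail) % 3]).translate())
    stop = prot.find("*")
    wt_prot_len = (cds_end - cds_start) // 3 - 1
    # image of the original stop start, same counting as above
    orig_stop = cds_end - 3
    stop_img = orig_stop
    deleted_orig_stop = any(s <= orig_stop < e for s, e in dels)
    for s, e in dels:
        stop_img -= min(e, orig_stop) - s if s < orig_stop else 0
    for p, seq in ins:
        if p <= orig_stop:
            stop_img += len(seq)
    if stop == -1:
        return "READTHROUGH"
    stop_pos = start_img + 3 * stop
    if not deleted_orig_stop and stop_pos == stop_img:
        return "RETAINED"
    if stop_pos < stop_img:
        return "PTC"
    return "READTHROUGH"


def simulate_splice_events(
    model: GeneModel,
    outcome_spec: Sequence[str],
    seed: int = 0,
    max_tries: int = 200,
) -> Tuple[List[SpliceEvent], dict]:
    """Construct one event per requested outcome, verified before emission.

    * RETAINED — a codon-aligned, stop-free internal deletion inside the CDS.
    * PTC — a frame-shifting deletion, or a stop-carrying cassette inserted
      at a CDS-internal exon junction (the cassette has a stop in every
      reading phase).
    * START_LOST — a deletion covering the start codon.
    """
    rng = _rng(seed, _STREAM_EVENTS)
    cds_start, cds_end = model.cds_start, model.cds_end
    n_codons = (cds_end - cds_start) // 3
    cum = model.exon_cumlens()
    cds_junctions = [j for j in cum[1:-1] if cds_start < j < cds_end - 3]

    events, truth_rows = [], []
    for k, outcome in enumerate(outcome_spec):
        if outcome not in ("RETAINED", "PTC", "START_LOST"):
            raise ValidationError(f"unknown requested outcome {outcome!r}")
        ev = None
        for attempt in range(max_tries):
            eid = f"E{k + 1}_{outcome[:3]}"
            if outcome == "RETAINED":
                if n_codons < 5:
                    raise ValidationError("CDS too short to plant a retained deletion")
                i = int(rng.integers(1, n_codons - 2))
                j = int(rng.integers(i + 1, n_codons - 1))
                cand = SpliceEvent(
                    eid,
                    EventKind.INTERNAL_DELETION,
                    cds_start + 3 * i,
                    cds_start + 3 * j,
                )
            elif outcome == "PTC":
                if cds_junctions and rng.random() < 0.5:
                    pos = cds_junctions[int(rng.integers(0, len(cds_junctions)))]
                    cand = SpliceEvent(
                        eid,
                        EventKind.CASSETTE_INSERTION,
                        start=pos,
                        inserted_sequence=_ALL_FRAME_STOP,
                    )
                else:
                    span = int(rng.integers(10, max(11, (cds_end - cds_start) // 4)))
                    span += (3 - span % 3) % 3 + 1  # force length % 3 != 0
                    s = int(rng.integers(cds_start + 3, max(cds_start + 4, cds_end - span - 3)))
                    cand = SpliceEvent(eid, EventKind.INTERNAL_DELETION, s, s + span)
            else:  # START_LOST
                s = max(0, cds_start - 1)
                cand = SpliceEvent(eid, EventKind.INTERNAL_DELETION, s, cds_start + 4)
            try:
                if _direct_outcome(model, cand) == outcome:
                    ev = cand
                    break
            except ValidationError:
                continue  # candidate coordinates fell off the transcript; redraw
        if ev is None:
            raise ValidationError(
                f"could not construct a {outcome} event in {max_tries} tries"
            )
        events.append(ev)
        truth_rows.append({"event_id": ev.event_id, "outcome": outcome})
    truth = {"seed": seed, "events": truth_rows}
    return events, truth


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------


def simulate_ortholog_table(
    n_genes: int,
    blocks: Sequence[Tuple[str, int]],
    noise: Optional[Dict[str, float]] = None,
    seed: int = 0,
    ref_chrom: str = "ref1",
    gene_spacing: int = 5000,
) -> Tuple[OrthologTable, dict]:
    """Reference genes in order, with planted target-chromosome runs.

    ``blocks`` lists (target_chrom, run_length) assigned to consecutive
    genes from the start of the segment; consecutive planted blocks must
    name different chromosomes (they would otherwise merge). Remaining
    genes alternate between two filler chromosomes (runs of one, so they
    never form blocks). ``noise`` holds ``unmapped_rate`` (chromosome
    assignment dropped) and ``relocation_rate`` (gene reassigned to a
    random other chromosome).
    """
    noise = {"unmapped_rate": 0.0, "relocation_rate": 0.0, **(noise or {})}
    rng = _rng(seed, _STREAM_ORTHO)
    planted_total = sum(n for _, n in blocks)
    if planted_total > n_genes:
        raise ValidationError("planted blocks exceed n_genes")
    for (c1, _), (c2, _) in zip(blocks, list(blocks)[1:]):
        if c1 == c2:
            raise ValidationError("consecutive planted blocks on one chromosome merge")

    chrom_assign: List[Optional[str]] = []
    planted = []
    g = 0
    for chrom, run in blocks:
        planted.append({"target_chrom": chrom, "gene_indices": list(range(g, g + run))})
        chrom_assign.extend([chrom] * run)
        g += run
    fillers = ["bgA", "bgB"]
    for i in range(n_genes - planted_total):
        chrom_assign.append(fillers[i % 2])

    pool = sorted({c for c, _ in blocks} | set(fillers))
    rows = []
    truth_noise = {"unmapped": [], "relocated": []}
    for i in range(n_genes):
        gid = f"g{i + 1:04d}"
        chrom = chrom_assign[i]
        tgt_gene = f"t_{gid}"
        if rng.random() < noise["relocation_rate"]:
            others = [c for c in pool if c != chrom]
            chrom = others[int(rng.integers(0, len(others)))]
            truth_noise["relocated"].append(gid)
        if rng.random() < noise["unmapped_rate"]:
            chrom = None
            truth_noise["unmapped"].append(gid)
        rows.append(
            {
                "ref_gene_id": gid,
                "ref_chrom": ref_chrom,
                "ref_start": 1000 + gene_spacing * i,
                "target_gene_id": tgt_gene,
                "target_chrom": chrom,
                "target_start": (1000 + gene_spacing * i) if chrom else pd.NA,
            }
        )
    df = pd.DataFrame(rows).astype({"target_chrom": "string"})
    for p in planted:
        p["ref_gene_ids"] = [rows[i]["ref_gene_id"] for i in p.pop("gene_indices")]
    truth = {"seed": seed, "planted_blocks": planted, "noise": truth_noise}
    return OrthologTable(df), truth


def tert_segment_synteny_example() -> OrthologTable:
    """Synthetic ortholog table reproducing the published segment tallies.

    Models the 70-gene reference chromosome segment around TERT: 61 genes
    with orthologs in the target genome, of which 46 map to chromosome X3,
    7 to X2 and a single relocated gene (the SRD5A1-like case) to X1; 7
    orthologs are not yet localised and 9 genes have no ortholog at all.
    Deterministic, built from the printed counts (synthetic stand-in for
    the deposited gene-by-gene table, which is not redistributed here).
    """
    rows = []
    spec = (
        [("X3", True)] * 46
        + [("X2", True)] * 7
        + [("X1", True)] * 1
        + [(None, True)] * 7
        + [(None, False)] * 9
    )
    for i, (chrom, has_orth) in enumerate(spec):
        gid = f"HSA5_{i + 1:03d}"
        rows.append(
            {
                "ref_gene_id": gid,
                "ref_chrom": "chr5",
                "ref_start": 100_000 + 400_000 * i,
                "target_gene_id": f"OAN_{i + 1:03d}" if has_orth else pd.NA,
                "target_chrom": chrom,
                "target_start": 50_000 + 300_000 * i if chrom else pd.NA,
            }
        )
    return OrthologTable(pd.DataFrame(rows).astype({"target_chrom": "string"}))


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def emit_family(data: FamilyData, out_dir) -> dict:
    """Write a simulated family's artifacts under one directory."""
    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": out / "family.fasta",
        "alignment": out / "family.aln.fasta",
        "domain_map": out / "family.domains.tsv",
        "truth": out / "truth.json",
    }
    tio.write_fasta(data.sequences, paths["sequences"])
    tio.write_alignment(data.alignment, paths["alignment"])
    tio.write_domain_map(data.domain_map, paths["domain_map"])
    paths["truth"].write_text(json.dumps(data.truth, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
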