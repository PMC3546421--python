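"""Core data containers shared across the toolkit.

Coordinate conventions
----------------------
Every internal coordinate is 0-based half-open. On-disk formats keep their
native conventions (GFF3 and the domain-map TSV are 1-based inclusive) and
are converted at the I/O boundary. Gene models are handled in transcript
orientation ('+' strand); minus-strand input is reverse-complemented at load.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZXUO")
DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class TertkitError(Exception):
    """Base class for every error the toolkit raises on bad input."""


class FormatError(TertkitError):
    """A file failed to parse; carries the location when known."""

    def __init__(self, message: str, path=None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc += ": "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class ValidationError(TertkitError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Sequences and alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence (protein or DNA)."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def validate_alphabet(self, alphabet: str) -> None:
        allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains characters outside the "
                f"{alphabet} alphabet: {sorted(bad)}"
            )


@dataclass
class Alignment:
    """A rectangular multiple alignment; gap character is '-'.

    Row order is meaningful and preserved by every operation.
    """

    ids: list
    rows: dict  # id -> aligned string

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise ValidationError("duplicate ids in alignment")
        lengths = {i: len(self.rows[i]) for i in self.ids}
        if len(set(lengths.values())) > 1:
            detail = ", ".join(f"{i}={n}" for i, n in lengths.items())
            raise ValidationError(f"ragged alignment rows: {detail}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[self.ids[0]]) if self.ids else 0

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[seq_id]
        except KeyError:
            raise ValidationError(f"id {seq_id!r} not in alignment") from None

    def to_char_matrix(self) -> np.ndarray:
        return np.array([list(self.rows[i]) for i in self.ids])

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        cols = list(cols)
        new = {i: "".join(self.rows[i][c] for c in cols) for i in self.ids}
        return Alignment(list(self.ids), new)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer residue-pair scores (e.g. BLOSUM62)."""

    alphabet: Tuple[str, ...]
    scores: Mapping[Tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise ValidationError(
                f"residue pair ({a!r}, {b!r}) not covered by the matrix"
            ) from None

    def validate(self) -> None:
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise ValidationError(f"missing matrix entry for ({a}, {b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ValidationError(
                        f"matrix not symmetric at ({a}, {b}): "
                        f"{self.scores[(a, b)]} != {self.scores[(b, a)]}"
                    )
        for a in "ACDEFGHIKLMNPQRSTVWY":
            if a in self.alphabet and self.scores[(a, a)] <= 0:
                raise ValidationError(f"non-positive diagonal for standard residue {a}")


# ---------------------------------------------------------------------------
# Gene models and splicing
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A single gene: genomic span, exon intervals and CDS anchors.

    ``cds_start``/``cds_end`` are *transcript* coordinates: offsets into the
    concatenation of exon substrings. ``cds_end`` is one past the stop codon.
    """

    gene_id: str
    sequence: str
    exons: list  # of (start, end) 0-based half-open genomic intervals
    cds_start: int
    cds_end: int

    def __post_init__(self):
        self.exons = [tuple(e) for e in self.exons]
        prev_end = 0
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValidationError(
                    f"exon ({s},{e}) outside sequence of length {len(self.sequence)}"
                )
            if s < prev_end:
                raise ValidationError(f"exons overlap or unsorted at ({s},{e})")
            prev_end = e
        tlen = self.transcript_length
        if not (0 <= self.cds_start < self.cds_end <= tlen):
            raise ValidationError(
                f"CDS anchors ({self.cds_start},{self.cds_end}) outside transcript "
                f"of length {tlen}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError("CDS length not a multiple of 3")
        tx = self.spliced_sequence()
        if tx[self.cds_start : self.cds_start + 3] != START_CODON:
            raise ValidationError("no ATG at cds_start on the canonical transcript")
        if tx[self.cds_end - 3 : self.cds_end] not in STOP_CODONS:
            raise ValidationError("no stop codon ending at cds_end")

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)

    def exon_cumlens(self) -> list:
        """Transcript coordinates of exon boundaries: [0, len(e1), len(e1)+len(e2), ...]."""
        cum = [0]
        for s, e in self.exons:
            cum.append(cum[-1] + (e - s))
        return cum

    def genomic_to_transcript(self, gpos: int) -> int:
        """Count of exonic bases strictly before genomic position ``gpos``."""
        t = 0
        for s, e in self.exons:
            if gpos >= e:
                t += e - s
            elif gpos > s:
                t += gpos - s
        return t


class EventKind(str, enum.Enum):
    ALT_DONOR_TO_ACCEPTOR = "alt_donor_to_acceptor"
    EXON_SKIP = "exon_skip"
    INTERNAL_DELETION = "internal_deletion"
    CASSETTE_INSERTION = "cassette_insertion"


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    Coordinate semantics by kind:

    * ``alt_donor_to_acceptor`` — ``start``/``end`` are a *genomic* half-open
      interval from the novel donor to the chosen acceptor; the exonic part
      of the interval is removed from the transcript.
    * ``exon_skip`` — ``exons`` lists 1-based exon numbers removed whole.
    * ``internal_deletion`` — ``start``/``end`` are *transcript* coordinates.
    * ``cassette_insertion`` — ``start`` is the transcript insertion point
      (must be an exon junction); ``inserted_sequence`` is the cassette.
    """

    event_id: str
    kind: EventKind
    start: Optional[int] = None
    end: Optional[int] = None
    exons: Tuple[int, ...] = ()
    inserted_sequence: str = ""

    def __post_init__(self):
        object.__setattr__(self, "kind", EventKind(self.kind))
        if self.kind is EventKind.CASSETTE_INSERTION and not self.inserted_sequence:
            raise ValidationError(
                f"event {self.event_id}: cassette_insertion needs a non-empty sequence"
            )
        if self.kind is EventKind.EXON_SKIP and not self.exons:
            raise ValidationError(f"event {self.event_id}: exon_skip with no exons listed")


class OrfStatus(str, enum.Enum):
    RETAINED = "RETAINED"
    PTC = "PTC"
    START_LOST = "START_LOST"
    READTHROUGH = "READTHROUGH"  # frame lost and no stop at/before the original's image


@dataclass
class OrfCall:
    """Reading-frame verdict for one mature transcript."""

    status: OrfStatus
    net_frame_shift: int
    stop_position: Optional[int]  # variant transcript coord of first in-frame stop
    protein_length: int  # residues before the stop (stop excluded)
    affected_domains: list = field(default_factory=list)
    utr_only: bool = False
    nmd_sensitive: Optional[bool] = None


@dataclass
class MatureTranscript:
    """A spliced transcript with per-segment provenance.

    ``provenance`` tiles the sequence: each element is either
    ``("genome", gstart, gend)`` or ``("insert:<event_id>", 0, len)``.
    """

    variant_ids: list
    sequence: str
    provenance: list
    # wild-type transcript-coordinate edits, kept for coordinate projection
    deletions: list = field(default_factory=list)  # sorted (start, end)
    insertions: list = field(default_factory=list)  # sorted (pos, seq, event_id)
    wt_length: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def image_of(self, wt_pos: int) -> int:
        """Variant coordinate where wild-type position ``wt_pos`` lands.

        If the position was deleted, returns the coordinate of the cut
        (the 'virtual image'). Insertions at a position land before it.
        """
        if not (0 <= wt_pos <= self.wt_length):
            raise ValidationError(f"wild-type position {wt_pos} out of range")
        deleted_before = sum(
            min(e, wt_pos) - s for s, e in self.deletions if s < wt_pos
        )
        inserted_before = sum(len(seq) for p, seq, _ in self.insertions if p <= wt_pos)
        return wt_pos - deleted_before + inserted_before

    def is_deleted(self, wt_pos: int) -> bool:
        return any(s <= wt_pos < e for s, e in self.deletions)

    def junction_positions(self) -> list:
        """Variant coordinates of the boundaries between provenance segments."""
        out, pos = [], 0
        for _, s, e in self.provenance[:-1]:
            pos += e - s
            out.append(pos)
        return out


@dataclass(frozen=True)
class VariantCombination:
    event_ids: Tuple[str, ...]
    valid: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# Domain maps and linker statistics
# ---------------------------------------------------------------------------

DOMAIN_ORDER = ("TEN", "TRBD", "RT", "CT")
LINKER_NAMES = ("L1", "L2", "L3")
# linker k sits strictly between these two named regions (reference coords)
LINKER_FLANKS = {"L1": ("TEN", "TRBD"), "L2": ("v-II", "v-III"), "L3": ("v-III", "QFP")}
MOTIF_HOME_DOMAIN = {
    "GQ": "TEN",
    "v-II": "TRBD",
    "v-III": "TRBD",
    "QFP": "TRBD",
    "T": "TRBD",
    "1": "RT",
    "2": "RT",
    "3": "RT",
    "A": "RT",
    "IFD": "RT",
    "B'": "RT",
    "C": "RT",
    "D": "RT",
    "E": "RT",
}


@dataclass
class DomainMap:
    """Named regions on a reference protein, 0-based half-open residue coords.

    ``regions`` holds domains and motifs; linker intervals are derived from
    their flanking regions when not given explicitly.
    """

    reference_id: str
    regions: dict  # name -> (start, end)
    reference_length: Optional[int] = None

    def __post_init__(self):
        for name, (s, e) in self.regions.items():
            if s > e or s < 0:
                raise ValidationError(f"region {name}: bad interval ({s},{e})")
            if self.reference_length is not None and e > self.reference_length:
                raise ValidationError(
                    f"region {name} ends at {e}, beyond reference length "
                    f"{self.reference_length}"
                )
        present = [d for d in DOMAIN_ORDER if d in self.regions]
        starts = [self.regions[d][0] for d in present]
        if starts != sorted(starts):
            raise ValidationError("domains out of order (expected TEN < TRBD < RT < CT)")
        for motif, home in MOTIF_HOME_DOMAIN.items():
            if motif in self.regions and home in self.regions:
                ms, me = self.regions[motif]
                hs, he = self.regions[home]
                if not (hs <= ms and me <= he):
                    raise ValidationError(f"motif {motif} not nested in domain {home}")

    def linker(self, name: str) -> Tuple[int, int]:
        """Reference residue interval of a linker (half-open, may be empty)."""
        if name in self.regions:
            return self.regions[name]
        up, down = LINKER_FLANKS[name]
        if up not in self.regions or down not in self.regions:
            raise ValidationError(
                f"cannot derive linker {name}: missing region {up!r} or {down!r}"
            )
        s = self.regions[up][1]
        e = self.regions[down][0]
        if s > e:
            raise ValidationError(f"linker {name} flanks overlap: {s} > {e}")
        return (s, e)

    def linkers(self) -> dict:
        return {k: self.linker(k) for k in LINKER_NAMES}


class LinkerClass(str, enum.Enum):
    LONG = "LONG"
    MEDIUM = "MEDIUM"
    SHORT = "SHORT"


@dataclass(frozen=True)
class LinkerProfile:
    species_id: str
    l1: int
    l2: int
    l3: int
    cumulative: int
    percent_of_reference: float
    linker_class: LinkerClass


@dataclass(frozen=True)
class SimilarityReport:
    reference_id: str
    target_id: str
    region: str
    similar_count: int
    reference_length_in_region: int
    percent: float


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

ORTHOLOG_COLUMNS = (
    "ref_gene_id",
    "ref_chrom",
    "ref_start",
    "target_gene_id",
    "target_chrom",
    "target_start",
)


@dataclass
class OrthologTable:
    """Gene-to-chromosome assignments: reference genes and their orthologs.

    Backed by a pandas DataFrame with columns `ORTHOLOG_COLUMNS`; absent
    ortholog / unmapped chromosome are pd.NA. Rows are ordered by
    (ref_chrom, ref_start).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ORTHOLOG_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(
                "ortholog table missing mandatory column(s) "
                f"{missing}; expected header: {list(ORTHOLOG_COLUMNS)}"
            )
        df = self.df.copy()
        df["ref_start"] = df["ref_start"].astype("int64")
        for col in ("ref_gene_id", "ref_chrom", "target_gene_id", "target_chrom"):
            df[col] = df[col].astype("string")
        df["target_start"] = pd.to_numeric(df["target_start"], errors="raise").astype(
            "Int64"
        )
        # an assigned chromosome without an ortholog gene is contradictory
        bad = df["target_gene_id"].isna() & df["target_chrom"].notna()
        if bad.any():
            raise ValidationError(
                f"rows with target_chrom but no target_gene_id: "
                f"{df.loc[bad, 'ref_gene_id'].tolist()}"
            )
        self.df = df.sort_values(["ref_chrom", "ref_start"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class SyntenyBlock:
    target_chrom: str
    ref_gene_ids: Tuple[str, ...]
    span: Tuple[int, int]  # (first ref_start, last ref_start)
    n_genes: int
    n_interrupting: int


def natural_sort_key(s: str):
    """Sort chromosome names numerically where possible (X2 < X10)."""
    import re

    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", str(s))]
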