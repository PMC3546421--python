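"""Readers and writers for every external format the pipeline touches.

Parsing of the standard formats is delegated to Biopython (FASTA, CLUSTAL,
NCBI substitution-matrix text), gffutils (GFF3 lines) and pandas (TSV);
this module adds the strict validation and located error reporting the
pipeline contracts require. All readers are total: a file either parses or
raises :class:`~tertkit.core.FormatError` / :class:`~tertkit.core.ValidationError`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

import pandas as pd
from Bio import AlignIO, Phylo, SeqIO
from Bio.Align import substitution_matrices
from gffutils.feature import feature_from_line

from .core import (
    Alignment,
    DomainMap,
    EventKind,
    FormatError,
    GeneModel,
    ORTHOLOG_COLUMNS,
    OrthologTable,
    SequenceRecord,
    SpliceEvent,
    SubstitutionMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _prescan_fasta(path) -> None:
    """Structural scan producing line-numbered errors Biopython would swallow."""
    header_line = None
    have_residues = False
    seen_any = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header_line is not None and not have_residues:
                    raise FormatError("empty sequence", path=path, line=header_line)
                if not line[1:].split():
                    raise FormatError("header with no id", path=path, line=lineno)
                header_line, have_residues, seen_any = lineno, False, True
            else:
                if header_line is None:
                    raise FormatError(
                        "sequence data before any '>' header", path=path, line=lineno
                    )
                have_residues = True
    if not seen_any:
        raise FormatError("no FASTA records found", path=path, line=1)
    if header_line is not None and not have_residues:
        raise FormatError("empty sequence", path=path, line=header_line)


def read_fasta(path, alphabet: Optional[str] = None) -> List[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Parameters
    ----------
    alphabet : {'protein', 'dna', None}
        When given, residues are validated against the IUPAC alphabet
        (protein including X, DNA including N).
    """
    _prescan_fasta(path)
    records, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}", path=path)
        seen.add(rec.id)
        sr = SequenceRecord(
            id=rec.id,
            description=rec.description[len(rec.id) :].strip(),
            residues=str(rec.seq).upper(),
        )
        if alphabet:
            sr.validate_alphabet(alphabet)
        records.append(sr)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

ALIGNMENT_DIALECTS = ("fasta", "clustal")


def read_alignment(path, dialect: str = "fasta") -> Alignment:
    """Read an aligned FASTA or CLUSTAL file.

    Gap characters '-' and '.' are both accepted and normalised to '-';
    residues are upper-cased. Ragged rows raise an error naming the
    offending ids and lengths.
    """
    if dialect not in ALIGNMENT_DIALECTS:
        raise ValidationError(f"unknown alignment dialect {dialect!r}")
    if dialect == "fasta":
        recs = read_fasta(path)
        ids = [r.id for r in recs]
        rows = {r.id: r.residues for r in recs}
    else:
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise FormatError(f"not a CLUSTAL file: {exc}", path=path) from exc
        ids = [r.id for r in aln]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate sequence id in alignment", path=path)
        rows = {r.id: str(r.seq).upper() for r in aln}
    rows = {i: s.replace(".", "-") for i, s in rows.items()}
    lengths = {i: len(rows[i]) for i in ids}
    if len(set(lengths.values())) > 1:
        detail = ", ".join(f"{i}={n}" for i, n in lengths.items())
        raise FormatError(f"ragged alignment rows: {detail}", path=path)
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path, width: int = 60) -> None:
    """Write an alignment as aligned FASTA."""
    write_fasta(
        [SequenceRecord(i, "", aln.rows[i]) for i in aln.ids], path, width=width
    )


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------


def _matrix_from_biopython(arr, source: str) -> SubstitutionMatrix:
    alphabet = list(arr.alphabet)
    if "*" in alphabet:
        emit = log.debug if source.startswith("builtin:") else log.warning
        emit("%s: dropping '*' row/column from substitution matrix", source)
        alphabet.remove("*")
    scores = {}
    for a in alphabet:
        for b in alphabet:
            v = float(arr[a, b])
            if v != int(v):
                raise FormatError(
                    f"non-integer score for ({a},{b}): {v}", path=source
                )
            scores[(a, b)] = int(v)
    m = SubstitutionMatrix(tuple(alphabet), scores)
    m.validate()
    return m


def read_substitution_matrix(path) -> SubstitutionMatrix:
    """Read an NCBI-format substitution matrix (e.g. BLOSUM62 text)."""
    try:
        arr = substitution_matrices.read(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse substitution matrix: {exc}", path=path) from exc
    return _matrix_from_biopython(arr, str(path))


def load_builtin_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load one of Biopython's bundled matrices by name (BLOSUM62, BLOSUM45, ...)."""
    try:
        arr = substitution_matrices.load(name)
    except Exception as exc:
        raise ValidationError(f"no builtin matrix named {name!r}") from exc
    return _matrix_from_biopython(arr, f"builtin:{name}")


# ---------------------------------------------------------------------------
# Gene models (GFF3 subset + FASTA)
# ---------------------------------------------------------------------------


def read_gene_model(gff_path, fasta_path) -> GeneModel:
    """Load a one-gene GFF3 subset (gene/mRNA/exon/CDS) plus its sequence.

    GFF3 coordinates are 1-based inclusive on disk and converted to 0-based
    half-open. Minus-strand models are reverse-complemented into transcript
    orientation with a logged notice.
    """
    seqs = read_fasta(fasta_path, alphabet="dna")
    if len(seqs) != 1:
        raise ValidationError(
            f"expected exactly one sequence in {fasta_path}, found {len(seqs)}"
        )
    seq = seqs[0].residues

    genes, exons, cds, strands = [], [], [], set()
    with open(gff_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"bad GFF3 line: {exc}", path=gff_path, line=lineno)
            iv = (feat.start - 1, feat.end)  # to 0-based half-open
            if feat.start > feat.end:
                raise FormatError(
                    f"start > end ({feat.start} > {feat.end})", path=gff_path, line=lineno
                )
            strands.add(feat.strand)
            ftype = feat.featuretype.lower()
            if ftype == "gene":
                genes.append((feat, iv))
            elif ftype == "exon":
                exons.append(iv)
            elif ftype == "cds":
                cds.append(iv)
    if len(genes) != 1:
        raise ValidationError(f"expected exactly one gene feature, found {len(genes)}")
    if not exons:
        raise ValidationError("gene model has no exon features")
    if not cds:
        raise ValidationError("gene model has no CDS features (missing CDS anchor)")
    strands.discard(".")
    if strands == {"-"}:
        log.info("minus-strand gene model: reverse-complementing into '+' orientation")
        n = len(seq)
        seq = reverse_complement(seq)
        exons = sorted((n - e, n - s) for s, e in exons)
        cds = sorted((n - e, n - s) for s, e in cds)
    elif strands not in ({"+"}, set()):
        raise ValidationError(f"mixed or unknown strands in gene model: {strands}")

    exons = sorted(exons)
    gene_feat, _ = genes[0]
    gene_id = gene_feat.attributes.get("ID", [gene_feat.id or "gene"])[0]

    # CDS anchors in transcript coordinates
    cds = sorted(cds)
    model_probe = _exonic_offset(exons, cds[0][0])
    cds_len = sum(e - s for s, e in cds)
    return GeneModel(
        gene_id=gene_id,
        sequence=seq,
        exons=exons,
        cds_start=model_probe,
        cds_end=model_probe + cds_len,
    )


def _exonic_offset(exons, gpos: int) -> int:
    t = 0
    for s, e in exons:
        if gpos >= e:
            t += e - s
        elif gpos >= s:
            return t + (gpos - s)
        else:
            raise ValidationError(f"genomic position {gpos} falls outside the exons")
    raise ValidationError(f"genomic position {gpos} falls outside the exons")


def write_gene_model(model: GeneModel, gff_path, fasta_path) -> None:
    """Emit a GeneModel as a one-gene GFF3 subset plus genome FASTA."""
    write_fasta([SequenceRecord(model.gene_id, "", model.sequence)], fasta_path)
    # project CDS transcript interval back onto the genome, split at exons
    cds_ivs = []
    t = 0
    for s, e in model.exons:
        lo = max(model.cds_start, t)
        hi = min(model.cds_end, t + (e - s))
        if lo < hi:
            cds_ivs.append((s + lo - t, s + hi - t))
        t += e - s
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        gmin = model.exons[0][0] + 1
        gmax = model.exons[-1][1]
        src = "tertkit"
        fh.write(
            f"{model.gene_id}\t{src}\tgene\t{gmin}\t{gmax}\t.\t+\t.\tID={model.gene_id}\n"
        )
        fh.write(
            f"{model.gene_id}\t{src}\tmRNA\t{gmin}\t{gmax}\t.\t+\t.\t"
            f"ID={model.gene_id}.t1;Parent={model.gene_id}\n"
        )
        for k, (s, e) in enumerate(model.exons, 1):
            fh.write(
                f"{model.gene_id}\t{src}\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID={model.gene_id}.exon{k};Parent={model.gene_id}.t1\n"
            )
        for k, (s, e) in enumerate(cds_ivs, 1):
            fh.write(
                f"{model.gene_id}\t{src}\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                f"ID={model.gene_id}.cds{k};Parent={model.gene_id}.t1\n"
            )


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------


def read_ortholog_table(path) -> OrthologTable:
    """Read the ortholog TSV (header exactly `ORTHOLOG_COLUMNS`, tab-separated)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype="string")
    except Exception as exc:
        raise FormatError(f"cannot read TSV: {exc}", path=path) from exc
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing mandatory column(s) {missing}; "
            f"expected header: {list(ORTHOLOG_COLUMNS)}",
            path=path,
        )
    try:
        return OrthologTable(df)
    except (ValidationError, FormatError):
        raise
    except Exception as exc:
        raise FormatError(f"bad ortholog table content: {exc}", path=path) from exc


def write_ortholog_table(table: OrthologTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, columns=list(ORTHOLOG_COLUMNS))


# ---------------------------------------------------------------------------
# Domain maps
# ---------------------------------------------------------------------------


def read_domain_map(path, reference_id: Optional[str] = None) -> DomainMap:
    """Read a domain/motif/linker TSV (region_name, kind, ref_start, ref_end).

    Coordinates on disk are 1-based inclusive on the reference protein. A
    ``#reference=<id>`` comment line sets the reference id unless overridden
    by the argument.
    """
    regions, ref = {}, reference_id
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#reference=") and ref is None:
                    ref = line.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if not header_seen:
                expected = ["region_name", "kind", "ref_start", "ref_end"]
                if parts[:4] != expected:
                    raise FormatError(
                        f"bad header {parts[:4]}; expected {expected}",
                        path=path,
                        line=lineno,
                    )
                header_seen = True
                continue
            if len(parts) < 4:
                raise FormatError("expected 4 tab-separated fields", path=path, line=lineno)
            name, kind, s, e = parts[0], parts[1], parts[2], parts[3]
            if kind not in ("domain", "motif", "linker"):
                raise FormatError(f"unknown region kind {kind!r}", path=path, line=lineno)
            try:
                regions[name] = (int(s) - 1, int(e))  # 1-based inclusive -> half-open
            except ValueError:
                raise FormatError("non-integer coordinate", path=path, line=lineno)
    if ref is None:
        raise ValidationError(
            "domain map needs a reference id (argument or '#reference=' line)"
        )
    return DomainMap(reference_id=ref, regions=regions)


def write_domain_map(dmap: DomainMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#reference={dmap.reference_id}\n")
        fh.write("region_name\tkind\tref_start\tref_end\n")
        for name, (s, e) in dmap.regions.items():
            if name in ("L1", "L2", "L3"):
                kind = "linker"
            elif name in ("TEN", "TRBD", "RT", "CT"):
                kind = "domain"
            else:
                kind = "motif"
            fh.write(f"{name}\t{kind}\t{s + 1}\t{e}\n")


# ---------------------------------------------------------------------------
# Splice events
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("event_id", "kind", "start", "end", "exons", "inserted_sequence")


def read_splice_events(path) -> List[SpliceEvent]:
    """Read the splice-event TSV (columns `EVENT_COLUMNS`; blanks where N/A)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype="string")
    except Exception as exc:
        raise FormatError(f"cannot read TSV: {exc}", path=path) from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing column(s) {missing}; expected header: {list(EVENT_COLUMNS)}",
            path=path,
        )
    events = []
    for _, row in df.iterrows():
        exons = ()
        if pd.notna(row["exons"]) and str(row["exons"]).strip():
            exons = tuple(int(x) for x in str(row["exons"]).split(","))
        events.append(
            SpliceEvent(
                event_id=str(row["event_id"]),
                kind=EventKind(str(row["kind"])),
                start=int(row["start"]) if pd.notna(row["start"]) else None,
                end=int(row["end"]) if pd.notna(row["end"]) else None,
                exons=exons,
                inserted_sequence=(
                    str(row["inserted_sequence"])
                    if pd.notna(row["inserted_sequence"])
                    else ""
                ),
            )
        )
    return events


def write_splice_events(events: Iterable[SpliceEvent], path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "kind": ev.kind.value,
                "start": "" if ev.start is None else ev.start,
                "end": "" if ev.end is None else ev.end,
                "exons": ",".join(str(x) for x in ev.exons),
                "inserted_sequence": ev.inserted_sequence,
            }
        )
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def write_newick(tree, path) -> None:
    """Serialise a Bio.Phylo tree as Newick with branch lengths."""
    Phylo.write(tree, str(path), "newick")
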