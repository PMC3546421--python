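"""Alternative-splicing arithmetic: derive mature transcripts from a gene
model plus splice events, and classify each variant's reading frame.

The model: a splice event edits the wild-type mature transcript — it either
removes a contiguous stretch of exonic sequence (novel donor/acceptor use,
exon skipping, internal deletion) or inserts a cassette at an exon junction.
All edits are normalised to wild-type transcript coordinates, applied
together, and the variant's reading frame is scanned from the image of the
original start codon. A variant retains the ORF when translation terminates
exactly at the image of the original stop codon; an in-frame stop strictly
upstream of that image is a premature termination codon (PTC), the signal
for nonsense-mediated decay.

Two events are compatible when their *footprints* — closed transcript-
coordinate intervals covering every base an event removes or inserts plus
the splice junctions it uses — are disjoint. Events that compete for the
same junction (e.g. a donor-truncation of exon 2 spliced to the exon-3
acceptor, versus a skip of exon 3) are thereby mutually exclusive even
though their deleted bases do not overlap.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, List, Optional, Sequence, Tuple

from .core import (
    EventKind,
    GeneModel,
    MatureTranscript,
    OrfCall,
    OrfStatus,
    SpliceEvent,
    STOP_CODONS,
    START_CODON,
    ValidationError,
    VariantCombination,
)

log = logging.getLogger(__name__)


class CombinationError(ValidationError):
    """Two splice events in one transcript have intersecting footprints."""


# ---------------------------------------------------------------------------
# Normalising events to transcript-coordinate edits
# ---------------------------------------------------------------------------


def _event_edits(
    model: GeneModel, event: SpliceEvent
) -> Tuple[List[Tuple[int, int]], List[Tuple[int, str]]]:
    """Return (deletions, insertions) in wild-type transcript coordinates.

    Deletions are half-open intervals; insertions are (position, sequence)
    with the cassette landing immediately before the position.
    """
    cum = model.exon_cumlens()
    tlen = cum[-1]
    kind = event.kind
    if kind is EventKind.ALT_DONOR_TO_ACCEPTOR:
        gs, ge = event.start, event.end
        if gs is None or ge is None or gs >= ge:
            raise ValidationError(f"event {event.event_id}: bad genomic interval")
        ts = model.genomic_to_transcript(gs)
        te = model.genomic_to_transcript(ge)
        if ts == te:
            raise ValidationError(
                f"event {event.event_id}: deleted genomic interval does not "
                "intersect the exon set"
            )
        return [(ts, te)], []
    if kind is EventKind.EXON_SKIP:
        dels = []
        for k in event.exons:
            if not (1 <= k <= len(model.exons)):
                raise ValidationError(
                    f"event {event.event_id}: no exon number {k} in the model"
                )
            dels.append((cum[k - 1], cum[k]))
        return sorted(dels), []
    if kind is EventKind.INTERNAL_DELETION:
        ts, te = event.start, event.end
        if ts is None or te is None or not (0 <= ts < te <= tlen):
            raise ValidationError(
                f"event {event.event_id}: bad transcript interval ({ts},{te})"
            )
        return [(ts, te)], []
    if kind is EventKind.CASSETTE_INSERTION:
        pos = event.start
        junctions = set(cum[1:-1])
        if pos not in junctions:
            raise ValidationError(
                f"event {event.event_id}: insertion point {pos} is not an "
                f"exon junction (junctions at {sorted(junctions)})"
            )
        return [], [(pos, event.inserted_sequence.upper())]
    raise ValidationError(f"unknown event kind {kind}")


def event_footprint(model: GeneModel, event: SpliceEvent) -> Tuple[int, int]:
    """Closed transcript-coordinate interval [lo, hi] the event occupies.

    Deletion endpoints are included so that two events sharing a splice
    junction intersect; a cassette insertion occupies its junction point.
    """
    dels, ins = _event_edits(model, event)
    points = [p for s, e in dels for p in (s, e)] + [p for p, _ in ins]
    return (min(points), max(points))


def events_compatible(
    model: GeneModel, a: SpliceEvent, b: SpliceEvent
) -> Tuple[bool, str]:
    la, ha = event_footprint(model, a)
    lb, hb = event_footprint(model, b)
    if la <= hb and lb <= ha:
        return False, (
            f"events {a.event_id} and {b.event_id} have intersecting transcript "
            f"footprints [{la},{ha}] and [{lb},{hb}]"
        )
    return True, ""


# ---------------------------------------------------------------------------
# Transcript derivation
# ---------------------------------------------------------------------------


def derive_transcript(
    model: GeneModel, events: Sequence[SpliceEvent]
) -> MatureTranscript:
    """Apply splice events to the gene model and return the mature transcript.

    Events must be pairwise compatible. Deletions are applied before
    insertions at equal coordinates; ties broken by event id.
    """
    events = sorted(events, key=lambda e: e.event_id)
    for a, b in itertools.combinations(events, 2):
        ok, reason = events_compatible(model, a, b)
        if not ok:
            raise CombinationError(reason)

    deletions: List[Tuple[int, int]] = []
    insertions: List[Tuple[int, str, str]] = []
    for ev in events:
        dels, ins = _event_edits(model, ev)
        deletions.extend(dels)
        insertions.extend((p, seq, ev.event_id) for p, seq in ins)
    deletions.sort()
    insertions.sort(key=lambda t: (t[0], t[2]))

    wt = model.spliced_sequence()
    tlen = len(wt)

    # walk the wild-type transcript emitting kept bases and cassettes
    ins_at = {}
    for p, seq, eid in insertions:
        ins_at.setdefault(p, []).append((seq, eid))
    del_iter = iter(deletions + [(tlen + 1, tlen + 1)])
    cur_del = next(del_iter)
    pieces: List[str] = []
    # provenance in wild-type transcript coords first, converted below
    segs: List[Tuple[str, int, int]] = []
    run_start = None

    def flush(end):
        nonlocal run_start
        if run_start is not None and end > run_start:
            segs.append(("wt", run_start, end))
        run_start = None

    pos = 0
    while pos <= tlen:
        if pos in ins_at:
            flush(pos)
            for seq, eid in ins_at[pos]:
                pieces.append(seq)
                segs.append((f"insert:{eid}", 0, len(seq)))
        if pos == tlen:
            break
        while pos >= cur_del[1]:
            cur_del = next(del_iter)
        if cur_del[0] <= pos < cur_del[1]:
            flush(pos)
            pos = cur_del[1]
            continue
        if run_start is None:
            run_start = pos
            pieces.append("")
        pieces[-1] += wt[pos]
        pos += 1
    flush(tlen)

    sequence = "".join(pieces)
    provenance = _wt_segments_to_genomic(model, segs)

    expected = tlen - sum(e - s for s, e in deletions) + sum(
        len(seq) for _, seq, _ in insertions
    )
    assert len(sequence) == expected, "length bookkeeping violated"
    return MatureTranscript(
        variant_ids=[e.event_id for e in events],
        sequence=sequence,
        provenance=provenance,
        deletions=deletions,
        insertions=insertions,
        wt_length=tlen,
    )


def _wt_segments_to_genomic(model: GeneModel, segs):
    """Split kept wild-type runs at exon boundaries into genomic intervals."""
    cum = model.exon_cumlens()
    out = []
    for src, s, e in segs:
        if src != "wt":
            out.append((src, s, e))
            continue
        for k, (gs, ge) in enumerate(model.exons):
            lo, hi = max(s, cum[k]), min(e, cum[k + 1])
            if lo < hi:
                out.append(("genome", gs + (lo - cum[k]), gs + (hi - cum[k])))
    return out


# ---------------------------------------------------------------------------
# ORF classification
# ---------------------------------------------------------------------------


def classify_orf(
    model: GeneModel,
    transcript: MatureTranscript,
    nmd_rule: Optional[int] = None,
) -> OrfCall:
    """Scan codons from the image of the original start and call the frame.

    * RETAINED — the first in-frame stop is the image of the original stop.
    * PTC — an in-frame stop strictly upstream of that image.
    * START_LOST — the original start codon was deleted or broken.
    * READTHROUGH — translation passes the original stop's image without
      terminating (frame lost, no upstream stop).

    With ``nmd_rule`` (nt), a PTC is additionally flagged NMD-sensitive when
    the stop starts at least that many nt upstream of the last exon–exon
    junction of the variant transcript.
    """
    seq = transcript.sequence
    cds_start, cds_end = model.cds_start, model.cds_end

    net_shift = _net_frame_shift(transcript, cds_start, cds_end)

    start_img = transcript.image_of(cds_start)
    if (
        transcript.is_deleted(cds_start)
        or seq[start_img : start_img + 3] != START_CODON
    ):
        return OrfCall(
            status=OrfStatus.START_LOST,
            net_frame_shift=net_shift,
            stop_position=None,
            protein_length=0,
        )

    orig_stop_img = transcript.image_of(cds_end - 3)
    orig_stop_deleted = transcript.is_deleted(cds_end - 3)

    stop_at = None
    for i in range(start_img, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            stop_at = i
            break

    if stop_at is not None and not orig_stop_deleted and stop_at == orig_stop_img:
        status = OrfStatus.RETAINED
        protein_len = (stop_at - start_img) // 3
        stop_position = None
    elif stop_at is not None and stop_at < orig_stop_img:
        status = OrfStatus.PTC
        protein_len = (stop_at - start_img) // 3
        stop_position = stop_at
    else:
        status = OrfStatus.READTHROUGH
        end = stop_at if stop_at is not None else len(seq) - (len(seq) - start_img) % 3
        protein_len = (end - start_img) // 3
        stop_position = stop_at

    nmd = None
    if nmd_rule is not None and status is OrfStatus.PTC:
        junctions = transcript.junction_positions()
        nmd = bool(junctions) and stop_position <= junctions[-1] - nmd_rule

    return OrfCall(
        status=status,
        net_frame_shift=net_shift,
        stop_position=stop_position,
        protein_length=protein_len,
        nmd_sensitive=nmd,
    )


def _net_frame_shift(transcript: MatureTranscript, cds_start: int, cds_end: int) -> int:
    """(inserted − deleted) mod 3 over the edits that shift the stop's frame.

    Only edits upstream of the stop codon's first base move the reading
    frame relative to the original stop; edits confined to the stop codon
    itself (or the UTRs) do not.
    """
    stop_start = cds_end - 3
    deleted = sum(
        max(0, min(e, stop_start) - max(s, cds_start)) for s, e in transcript.deletions
    )
    inserted = sum(
        len(seq)
        for p, seq, _ in transcript.insertions
        if cds_start < p <= stop_start
    )
    return (inserted - deleted) % 3


# ---------------------------------------------------------------------------
# Combinations and per-variant reports
# ---------------------------------------------------------------------------


def enumerate_combinations(
    model: GeneModel, events: Sequence[SpliceEvent], max_events: int
) -> List[VariantCombination]:
    """All event subsets of size 1..max_events with validity verdicts.

    Output in lexicographic order of the event-id tuple.
    """
    if max_events < 1:
        raise ValidationError("max_events must be >= 1")
    events = sorted(events, key=lambda e: e.event_id)
    out = []
    for size in range(1, max_events + 1):
        for combo in itertools.combinations(events, size):
            valid, reason = True, ""
            for a, b in itertools.combinations(combo, 2):
                ok, why = events_compatible(model, a, b)
                if not ok:
                    valid, reason = False, why
                    break
            out.append(
                VariantCombination(tuple(e.event_id for e in combo), valid, reason)
            )
    out.sort(key=lambda c: (len(c.event_ids), c.event_ids))
    return out


def summarize_variant(
    model: GeneModel,
    event: SpliceEvent,
    domain_map_on_protein: Optional[dict] = None,
    nmd_rule: Optional[int] = None,
) -> OrfCall:
    """Classify a single-event variant and report the domains it disrupts.

    ``domain_map_on_protein`` maps domain name -> (start, end) half-open
    residue intervals on the wild-type protein. The event footprint is
    projected through protein coordinates: residue = (pos − cds_start) // 3.
    An event entirely outside the CDS yields an empty list, noted UTR-only.
    """
    transcript = derive_transcript(model, [event])
    call = classify_orf(model, transcript, nmd_rule=nmd_rule)
    lo, hi = event_footprint(model, event)
    cds_start, cds_end = model.cds_start, model.cds_end
    if hi < cds_start or lo >= cds_end:
        call.utr_only = True
        call.affected_domains = []
        return call
    aa_lo = max(0, (lo - cds_start) // 3)
    aa_hi = min((cds_end - cds_start) // 3, (min(hi, cds_end - 1) - cds_start) // 3 + 1)
    affected = []
    for name, (s, e) in (domain_map_on_protein or {}).items():
        if s < aa_hi and aa_lo < e:
            affected.append(name)
    call.affected_domains = sorted(affected)
    return call
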