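"""Transcript derivation, ORF/PTC classification, and event combinations.

The classifier is checked against an independent full-translation oracle
that applies each event by plain string surgery and translates with
Biopython, sharing no code with the implementation under test.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from tertkit import EventKind, OrfStatus, SpliceEvent, ValidationError
from tertkit.platypus_model import (
    CASSETTE_LEN,
    EXPECTED_STATUS,
    ORF_LEN,
    PROTEIN_DOMAINS,
    TRANSCRIPT_LEN,
)
from tertkit.splicing import (
    CombinationError,
    classify_orf,
    derive_transcript,
    enumerate_combinations,
    summarize_variant,
)
from tertkit.simulate import simulate_gene_model


# ---------------------------------------------------------------------------
# Independent oracle: string surgery + Bio.Seq translation
# ---------------------------------------------------------------------------


def translation_oracle(model, event):
    """Full-translation verdict for a single deletion/insertion event."""
    wt = model.spliced_sequence()
    cs, ce = model.cds_start, model.cds_end
    if event.kind is EventKind.INTERNAL_DELETION:
        s, e = event.start, event.end
        edited = wt[:s] + wt[e:]
        if s <= cs < e:
            return "START_LOST"
        start = cs - (e - s) if e <= cs else cs
        stop_img = ce - 3
        stop_deleted = s <= ce - 3 < e
        if s < ce - 3:
            stop_img -= min(e, ce - 3) - s
    elif event.kind is EventKind.CASSETTE_INSERTION:
        p, ins = event.start, event.inserted_sequence
        edited = wt[:p] + ins + wt[p:]
        start = cs + len(ins) if p <= cs else cs
        stop_img = ce - 3 + (len(ins) if p <= ce - 3 else 0)
        stop_deleted = False
    else:
        raise NotImplementedError(event.kind)
    if edited[start : start + 3] != "ATG":
        return "START_LOST"
    tail = edited[start:]
    prot = str(Seq(tail[: len(tail) - len(tail) % 3]).translate())
    i = prot.find("*")
    if i == -1:
        return "READTHROUGH"
    pos = start + 3 * i
    if not stop_deleted and pos == stop_img:
        return "RETAINED"
    return "PTC" if pos < stop_img else "READTHROUGH"


def _random_single_events(model, rng, n):
    """Random deletions and junction insertions across the transcript."""
    tlen = model.transcript_length
    junctions = model.exon_cumlens()[1:-1]
    out = []
    for k in range(n):
        if rng.random() < 0.75 or not junctions:
            s = int(rng.integers(0, tlen - 2))
            e = int(rng.integers(s + 1, min(tlen, s + 1 + int(rng.integers(1, 900)))))
            out.append(SpliceEvent(f"r{k}", EventKind.INTERNAL_DELETION, s, e))
        else:
            p = junctions[int(rng.integers(0, len(junctions)))]
            ins = "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, size=int(rng.integers(1, 60)))]
            )
            out.append(
                SpliceEvent(f"r{k}", EventKind.CASSETTE_INSERTION, start=p,
                            inserted_sequence=ins)
            )
    return out


# ---------------------------------------------------------------------------
# derive_transcript
# ---------------------------------------------------------------------------


class TestDeriveTranscript:
    def test_no_events_is_exon_concatenation(self, platypus):
        model, _ = platypus
        tr = derive_transcript(model, [])
        assert tr.sequence == model.spliced_sequence()
        assert tr.length == sum(e - s for s, e in model.exons) == TRANSCRIPT_LEN

    def test_cassette_insertion_adds_its_length(self, platypus):
        model, events = platypus
        tr = derive_transcript(model, [events["D"]])
        assert tr.length == TRANSCRIPT_LEN + CASSETTE_LEN  # 25-nt cassette

    def test_exon_skip_matches_naive_concatenation(self):
        rng = np.random.default_rng(42)
        for seed in range(5):
            model = simulate_gene_model(n_exons=8, seed=seed, orf_nt=1200, utr3=80)
            skip = tuple(
                sorted(rng.choice(range(2, 8), size=int(rng.integers(1, 3)),
                                  replace=False).tolist())
            )
            tr = derive_transcript(
                model, [SpliceEvent("sk", EventKind.EXON_SKIP, exons=skip)]
            )
            naive = "".join(
                model.sequence[s:e]
                for k, (s, e) in enumerate(model.exons, 1)
                if k not in skip
            )
            assert tr.sequence == naive

    def test_length_bookkeeping_conservation(self, platypus):
        model, events = platypus
        for name, ev in events.items():
            tr = derive_transcript(model, [ev])
            deleted = sum(e - s for s, e in tr.deletions)
            inserted = sum(len(seq) for _, seq, _ in tr.insertions)
            assert tr.length == TRANSCRIPT_LEN - deleted + inserted

    def test_provenance_tiles_sequence(self, platypus):
        model, events = platypus
        for chosen in ([], [events["A"]], [events["A"], events["D"]]):
            tr = derive_transcript(model, chosen)
            assert sum(e - s for _, s, e in tr.provenance) == tr.length

    def test_incompatible_pair_cites_events(self, platypus):
        model, events = platypus
        with pytest.raises(CombinationError, match="A.*B|B.*A"):
            derive_transcript(model, [events["A"], events["B"]])


# ---------------------------------------------------------------------------
# classify_orf
# ---------------------------------------------------------------------------


class TestClassifyOrf:
    def test_wild_type_protein_length(self, platypus):
        model, _ = platypus
        call = classify_orf(model, derive_transcript(model, []))
        assert call.status is OrfStatus.RETAINED
        assert call.protein_length == 1296  # 3891-nt ORF incl. start+stop
        assert call.net_frame_shift == 0

    def test_long_in_frame_stop_free_deletion_retained(self, platypus):
        model, _ = platypus
        cs = model.cds_start
        ev = SpliceEvent("big", EventKind.INTERNAL_DELETION, cs + 3, cs + 3 + 3000)
        call = classify_orf(model, derive_transcript(model, [ev]))
        assert call.status is OrfStatus.RETAINED
        assert call.protein_length == 1296 - 1000

    def test_start_deletion_is_start_lost_not_ptc(self, platypus):
        model, _ = platypus
        ev = SpliceEvent("nostart", EventKind.INTERNAL_DELETION, 0, model.cds_start + 3)
        call = classify_orf(model, derive_transcript(model, [ev]))
        assert call.status is OrfStatus.START_LOST

    def test_matches_translation_oracle_on_random_events(self):
        """>=1000 random single events agree with the full-translation oracle."""
        rng = np.random.default_rng(7)
        disagreements = []
        for seed in range(4):
            model = simulate_gene_model(n_exons=10, seed=seed, orf_nt=2400, utr3=150)
            for ev in _random_single_events(model, rng, 260):
                tr = derive_transcript(model, [ev])
                got = classify_orf(model, tr).status.value
                want = translation_oracle(model, ev)
                if got != want:
                    disagreements.append((seed, ev, got, want))
        assert not disagreements, disagreements[:3]

    def test_frame_law_non_triple_never_retained(self):
        """An event with net CDS length change not 0 mod 3 cannot retain the ORF."""
        rng = np.random.default_rng(13)
        model = simulate_gene_model(n_exons=10, seed=21, orf_nt=2400, utr3=150)
        cs, ce = model.cds_start, model.cds_end
        for ev in _random_single_events(model, rng, 400):
            tr = derive_transcript(model, [ev])
            call = classify_orf(model, tr)
            if call.net_frame_shift != 0:
                assert call.status is not OrfStatus.RETAINED

    def test_nmd_rule_flags_distant_ptc(self, platypus):
        model, events = platypus
        tr = derive_transcript(model, [events["B"]])  # early frameshift PTC
        call = classify_orf(model, tr, nmd_rule=50)
        assert call.status is OrfStatus.PTC
        assert call.nmd_sensitive is True


# ---------------------------------------------------------------------------
# The packaged worked example (variants A..D)
# ---------------------------------------------------------------------------


class TestPlatypusVariants:
    def test_published_status_table_reproduced(self, platypus):
        """Exactly A and A4 retain the ORF; A2, A3, B, C, D carry PTCs."""
        model, events = platypus
        got = {
            name: classify_orf(model, derive_transcript(model, [ev])).status
            for name, ev in events.items()
        }
        assert got == EXPECTED_STATUS
        retained = {n for n, s in got.items() if s is OrfStatus.RETAINED}
        assert retained == {"A", "A4"}

    def test_two_of_four_second_exon_variants_retain_orf(self, platypus):
        model, events = platypus
        second_exon = ["A", "A2", "A3", "A4"]
        n_ret = sum(
            classify_orf(model, derive_transcript(model, [events[n]])).status
            is OrfStatus.RETAINED
            for n in second_exon
        )
        assert n_ret == 2

    def test_cassette_frameshifts_by_one(self, platypus):
        model, events = platypus
        tr = derive_transcript(model, [events["D"]])
        assert classify_orf(model, tr).net_frame_shift == 25 % 3


# ---------------------------------------------------------------------------
# Combinations
# ---------------------------------------------------------------------------


class TestCombinations:
    def test_singles_all_valid(self, platypus):
        model, events = platypus
        singles = [
            c for c in enumerate_combinations(model, list(events.values()), 1)
        ]
        assert len(singles) == 7 and all(c.valid for c in singles)

    def test_mutual_exclusivity_of_second_exon_and_b(self, platypus):
        """A..A4 and B are pairwise exclusive; each combines with C or D."""
        model, events = platypus
        pairs = {
            c.event_ids: c.valid
            for c in enumerate_combinations(model, list(events.values()), 2)
            if len(c.event_ids) == 2
        }
        exclusive = ["A", "A2", "A3", "A4", "B"]
        for i, a in enumerate(exclusive):
            for b in exclusive[i + 1 :]:
                assert pairs[tuple(sorted((a, b)))] is False
        for a in exclusive:
            for b in ("C", "D"):
                assert pairs[tuple(sorted((a, b)))] is True
        assert pairs[("C", "D")] is True

    def test_validity_matches_interval_intersection_oracle(self):
        """Random event sets: verdicts equal a brute-force footprint check."""
        from tertkit.splicing import event_footprint

        rng = np.random.default_rng(3)
        model = simulate_gene_model(n_exons=6, seed=9, orf_nt=900, utr3=60)
        events = _random_single_events(model, rng, 8)
        combos = enumerate_combinations(model, events, 2)
        for c in (c for c in combos if len(c.event_ids) == 2):
            by_id = {e.event_id: e for e in events}
            (l1, h1), (l2, h2) = (
                event_footprint(model, by_id[i]) for i in c.event_ids
            )
            overlap = l1 <= h2 and l2 <= h1
            assert c.valid == (not overlap)

    def test_deterministic_lexicographic_order(self, platypus):
        model, events = platypus
        combos = enumerate_combinations(model, list(events.values()), 2)
        keys = [(len(c.event_ids), c.event_ids) for c in combos]
        assert keys == sorted(keys)

    def test_max_events_below_one_rejected(self, platypus):
        model, events = platypus
        with pytest.raises(ValidationError):
            enumerate_combinations(model, list(events.values()), 0)


# ---------------------------------------------------------------------------
# summarize_variant
# ---------------------------------------------------------------------------


class TestSummarizeVariant:
    def test_reports_overlapped_domains(self, platypus):
        model, events = platypus
        call = summarize_variant(model, events["C"], PROTEIN_DOMAINS)
        # variant C removes exons 7-9's first half: residues ~483..696 (TRBD)
        assert "TRBD" in call.affected_domains
        assert not call.utr_only

    def test_utr_only_event_yields_empty_domain_list(self, platypus):
        model, _ = platypus
        ev = SpliceEvent(
            "utr", EventKind.INTERNAL_DELETION, TRANSCRIPT_LEN - 100, TRANSCRIPT_LEN - 10
        )
        call = summarize_variant(model, ev, PROTEIN_DOMAINS)
        assert call.utr_only and call.affected_domains == []
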