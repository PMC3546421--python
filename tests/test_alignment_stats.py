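"""Column filtering, similarity percentages, linker extraction and classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tertkit import Alignment, LinkerClass, ValidationError
from tertkit.alnstats import (
    classify_linker,
    distance_matrix,
    domain_similarity_table,
    extract_linker_lengths,
    filter_columns,
    map_reference_positions_to_columns,
    pairwise_similarity,
)
from tertkit.simulate import FamilyProfile, simulate_tert_family


def aln_of(*rows):
    ids = [f"s{i}" for i in range(len(rows))]
    return Alignment(ids, dict(zip(ids, rows)))


# ---------------------------------------------------------------------------
# filter_columns
# ---------------------------------------------------------------------------

random_alignments = st.integers(0, 10_000).map(
    lambda seed: _random_aln(np.random.default_rng(seed))
)


def _random_aln(rng):
    n_rows = int(rng.integers(2, 6))
    n_cols = int(rng.integers(1, 25))
    chars = np.array(list("ACDEFX-"))
    rows = ["".join(chars[rng.integers(0, len(chars), n_cols)]) for _ in range(n_rows)]
    return aln_of(*rows)


class TestFilterColumns:
    def test_zero_tolerance_strips_gap_and_x_columns(self):
        aln = aln_of("MK-WX", "MKYWA", "MKYWA")
        out, kept = filter_columns(aln, 0.0, treat_x_as_gap=True)
        assert kept == [0, 1, 3]
        assert out.rows["s0"] == "MKW"
        for i in out.ids:  # the published 0%-tolerance contract
            assert "-" not in out.rows[i] and "X" not in out.rows[i]

    def test_gap_free_alignment_unchanged_at_any_tolerance(self):
        aln = aln_of("MKYW", "MRYW")
        for tol in (0.0, 0.5, 1.0):
            out, kept = filter_columns(aln, tol)
            assert out.rows == aln.rows and kept == [0, 1, 2, 3]

    def test_x_kept_when_not_treated_as_gap(self):
        aln = aln_of("MX", "MA")
        _, kept = filter_columns(aln, 0.0, treat_x_as_gap=False)
        assert kept == [0, 1]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(aln=random_alignments, tol_pct=st.integers(0, 100))
    def test_matches_brute_force_column_scan(self, aln, tol_pct):
        tol = tol_pct / 100
        _, kept = filter_columns(aln, tol, treat_x_as_gap=True)
        expect = [
            c
            for c in range(aln.n_cols)
            if sum(aln.rows[i][c] in "-X" for i in aln.ids) / aln.n_rows <= tol
        ]
        assert kept == expect

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(aln=random_alignments, t1=st.integers(0, 100), t2=st.integers(0, 100))
    def test_idempotent_and_monotone_in_tolerance(self, aln, t1, t2):
        lo, hi = sorted((t1 / 100, t2 / 100))
        out_lo, kept_lo = filter_columns(aln, lo)
        _, kept_again = filter_columns(out_lo, lo)
        assert kept_again == list(range(out_lo.n_cols))  # idempotent
        _, kept_hi = filter_columns(aln, hi)
        assert set(kept_lo) <= set(kept_hi)  # monotone


# ---------------------------------------------------------------------------
# pairwise similarity
# ---------------------------------------------------------------------------


class TestPairwiseSimilarity:
    def test_identical_rows_100_percent(self, blosum62):
        aln = aln_of("MKYW", "MKYW")
        assert pairwise_similarity(aln, blosum62, "s0", "s1").percent == 100.0

    def test_self_similarity_100_even_with_x(self, blosum62):
        aln = aln_of("MKXW-", "MAYWA")
        assert pairwise_similarity(aln, blosum62, "s0", "s0").percent == 100.0

    def test_hand_checked_blosum62_example(self, blosum62):
        # K~R scores 2 (>0: similar), R~K similar, W vs gap not; ref gap
        # column excluded from the denominator: 2 of 3 -> 66.7%
        aln = aln_of("KR-W", "RKY-")
        rep = pairwise_similarity(aln, blosum62, "s0", "s1")
        assert (rep.similar_count, rep.reference_length_in_region) == (2, 3)
        assert rep.percent == pytest.approx(200 / 3)

    def test_all_gap_target_zero(self, blosum62):
        aln = aln_of("MKYW", "----")
        assert pairwise_similarity(aln, blosum62, "s0", "s1").percent == 0.0

    def test_x_never_similar_to_other_residues(self, blosum62):
        aln = aln_of("XXX", "LLX")
        rep = pairwise_similarity(aln, blosum62, "s0", "s1")
        assert rep.similar_count == 1  # only the X==X identity column

    def test_not_symmetric_by_construction(self, blosum62):
        # reference-length denominators differ when one row is gappier
        aln = aln_of("MKYW", "MK--")
        fwd = pairwise_similarity(aln, blosum62, "s0", "s1").percent
        rev = pairwise_similarity(aln, blosum62, "s1", "s0").percent
        assert fwd == 50.0 and rev == 100.0 and fwd != rev


class TestReferencePositionMapping:
    def test_positions_map_through_gaps(self):
        aln = aln_of("M-KY--W", "MAKYAAW")
        cols = map_reference_positions_to_columns(aln, "s0", [0, 1, 2, 3])
        assert cols == [0, 2, 3, 6]

    def test_position_beyond_reference_errors(self):
        aln = aln_of("M-KY", "MAKY")
        with pytest.raises(ValidationError, match="beyond"):
            map_reference_positions_to_columns(aln, "s0", [3])


# ---------------------------------------------------------------------------
# linkers
# ---------------------------------------------------------------------------


class TestLinkers:
    def test_reference_recovers_its_own_lengths(self, planted_family):
        profs = {p.species_id: p for p in
                 extract_linker_lengths(planted_family.alignment,
                                        planted_family.domain_map)}
        ref = profs["ref"]
        assert (ref.l1, ref.l2, ref.l3) == (150, 100, 50)
        assert ref.percent_of_reference == 100.0
        assert ref.linker_class is LinkerClass.LONG

    def test_planted_lengths_recovered_exactly(self, planted_family):
        """Generator truth: every species' linkers read back from the alignment."""
        truth = planted_family.truth
        profs = {p.species_id: p for p in
                 extract_linker_lengths(planted_family.alignment,
                                        planted_family.domain_map)}
        for sp, (l1, l2, l3) in zip(truth["species"], truth["linker_lengths"]):
            assert (profs[sp].l1, profs[sp].l2, profs[sp].l3) == (l1, l2, l3)

    def test_planted_classes_recovered(self, planted_family):
        # cumulative 300/300, 300/300(=100%), 180/300(=60%), 60/300(=20%)
        profs = {p.species_id: p.linker_class for p in
                 extract_linker_lengths(planted_family.alignment,
                                        planted_family.domain_map)}
        assert profs == {
            "ref": LinkerClass.LONG,
            "longy": LinkerClass.LONG,
            "mediumy": LinkerClass.MEDIUM,
            "shorty": LinkerClass.SHORT,
        }

    def test_all_gapped_species_is_short_with_zero(self):
        fam = simulate_tert_family(
            FamilyProfile(
                n_species=2,
                linker_lengths=[(20, 15, 10), (0, 0, 0)],
                species_ids=["ref", "gappy"],
                seed=4,
            )
        )
        profs = {p.species_id: p for p in
                 extract_linker_lengths(fam.alignment, fam.domain_map)}
        assert profs["gappy"].cumulative == 0
        assert profs["gappy"].linker_class is LinkerClass.SHORT


class TestClassifyLinker:
    @pytest.mark.parametrize(
        "percent,expected",
        [
            (100.0, LinkerClass.LONG),
            (160.0, LinkerClass.LONG),
            (175.0, LinkerClass.LONG),  # beyond the observed max, still LONG
            (99.999, LinkerClass.MEDIUM),
            (60.0, LinkerClass.MEDIUM),
            (59.999, LinkerClass.SHORT),
            (0.0, LinkerClass.SHORT),
        ],
    )
    def test_boundaries(self, percent, expected):
        assert classify_linker(percent) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            classify_linker(-1.0)


# ---------------------------------------------------------------------------
# domain similarity table
# ---------------------------------------------------------------------------


class TestDomainSimilarityTable:
    def test_zero_rate_family_fully_similar(self, blosum62):
        fam = simulate_tert_family(
            FamilyProfile(n_species=3, domain_sub_rate=0.0, seed=8)
        )
        table = domain_similarity_table(
            fam.alignment, blosum62, "ref", fam.domain_map
        )
        domains = table[table.region != "FULL"]
        assert (domains.percent == 100.0).all()

    def test_trbd_excludes_internal_linkers(self, planted_family, blosum62):
        dmap = planted_family.domain_map
        table = domain_similarity_table(
            planted_family.alignment, blosum62, "ref", dmap
        )
        trbd = table[table.region == "TRBD"].iloc[0]
        l2 = dmap.linker("L2")
        l3 = dmap.linker("L3")
        trbd_len = dmap.regions["TRBD"][1] - dmap.regions["TRBD"][0]
        expected = trbd_len - (l2[1] - l2[0]) - (l3[1] - l3[0])
        assert trbd.reference_length_in_region == expected

    def test_row_order_deterministic(self, planted_family, blosum62):
        t1 = domain_similarity_table(
            planted_family.alignment, blosum62, "ref", planted_family.domain_map
        )
        t2 = domain_similarity_table(
            planted_family.alignment, blosum62, "ref", planted_family.domain_map
        )
        assert t1.equals(t2)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, planted_family, blosum62):
        ids, d = distance_matrix(planted_family.alignment, blosum62)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_identical_rows_distance_zero(self, blosum62):
        aln = aln_of("MKYW", "MKYW", "AAAA")
        _, d = distance_matrix(aln, blosum62)
        assert d[0, 1] == 0.0 and d[0, 2] > 0.0
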