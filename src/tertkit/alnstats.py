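"""Domain-anchored statistics over protein multiple alignments.

Covers the comparative-architecture analyses: stripping alignment columns
by gap tolerance (the 0%-tolerance setting removes every column holding a
gap or an X), reference-relative similarity percentages under a
substitution matrix, linker-length extraction between annotated domains
and motifs, the cumulative linker statistic with its long/medium/short
classification, and substitution-based distances for tree plumbing.

Similarity convention: a reference residue counts as similar when the
target row holds, at the same column, a residue scoring at least
``min_score`` (default 1, i.e. strictly positive) in the matrix. Exact
identity always counts; 'X' against any *different* residue never does.
The denominator is the number of reference (non-gap) residues in the
region, so similarity is not symmetric between two sequences of unequal
length.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import (
    GAP,
    Alignment,
    DomainMap,
    LinkerClass,
    LinkerProfile,
    SimilarityReport,
    SubstitutionMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

# linker-class boundaries, percent of the reference cumulative length:
# short < 60 <= medium < 100 <= long; 160 is the largest value observed
# in the comparative data, logged (not capped) when exceeded
SHORT_BELOW = 60.0
LONG_FROM = 100.0
OBSERVED_MAX = 160.0


# ---------------------------------------------------------------------------
# Column filtering
# ---------------------------------------------------------------------------


def filter_columns(
    aln: Alignment,
    gap_tolerance: float = 0.0,
    treat_x_as_gap: bool = True,
) -> Tuple[Alignment, List[int]]:
    """Keep the columns whose gap (and X, when flagged) fraction <= tolerance.

    Returns the filtered alignment and the kept 0-based column indices.
    With tolerance 0 every column containing a gap or an X is removed.
    """
    if not 0.0 <= gap_tolerance <= 1.0:
        raise ValidationError(f"gap tolerance {gap_tolerance} outside [0,1]")
    if aln.n_rows == 0:
        raise ValidationError("empty alignment")
    mat = aln.to_char_matrix()
    bad = mat == GAP
    if treat_x_as_gap:
        bad |= mat == "X"
    frac = bad.mean(axis=0)
    kept = [int(c) for c in np.nonzero(frac <= gap_tolerance)[0]]
    return aln.take_columns(kept), kept


# ---------------------------------------------------------------------------
# Reference-position bookkeeping
# ---------------------------------------------------------------------------


def map_reference_positions_to_columns(
    aln: Alignment, reference_id: str, positions: Sequence[int]
) -> List[int]:
    """Column index of each reference residue position (0-based, ungapped)."""
    row = aln.row(reference_id)
    residue_cols = [c for c, ch in enumerate(row) if ch != GAP]
    out = []
    for p in positions:
        if not 0 <= p < len(residue_cols):
            raise ValidationError(
                f"reference position {p} beyond ungapped length {len(residue_cols)}"
            )
        out.append(residue_cols[p])
    return out


def _region_columns(
    aln: Alignment, reference_id: str, interval: Tuple[int, int]
) -> List[int]:
    """All columns spanned by a reference residue interval [s, e).

    Includes reference-gap columns lying between the flanking residues, so
    that insertions relative to the reference stay inside their region.
    """
    s, e = interval
    row = aln.row(reference_id)
    residue_cols = [c for c, ch in enumerate(row) if ch != GAP]
    n = len(residue_cols)
    if s > n or e > n:
        raise ValidationError(
            f"region ({s},{e}) outside reference of ungapped length {n}"
        )
    lo = residue_cols[s] if s < n else aln.n_cols
    if s == e:
        return []
    hi = residue_cols[e - 1] + 1
    return list(range(lo, hi))


def _band_between(
    aln: Alignment, reference_id: str, upstream_last: int, downstream_first: int
) -> List[int]:
    """Columns strictly between two reference residues (by residue index).

    ``upstream_last`` may be -1 (band starts at column 0) and
    ``downstream_first`` may equal the reference length (band runs to the
    final column).
    """
    row = aln.row(reference_id)
    residue_cols = [c for c, ch in enumerate(row) if ch != GAP]
    lo = residue_cols[upstream_last] + 1 if upstream_last >= 0 else 0
    hi = (
        residue_cols[downstream_first]
        if downstream_first < len(residue_cols)
        else aln.n_cols
    )
    return list(range(lo, hi))


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------


def _is_similar(a: str, b: str, matrix: SubstitutionMatrix, min_score: int) -> bool:
    if a == GAP or b == GAP:
        return False
    if a == b:
        return True
    if a == "X" or b == "X":
        return False
    try:
        return matrix.score(a, b) >= min_score
    except ValidationError:
        return False


def pairwise_similarity(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    reference_id: str,
    target_id: str,
    region: Optional[str] = None,
    domain_map: Optional[DomainMap] = None,
    min_score: int = 1,
    columns: Optional[Sequence[int]] = None,
) -> SimilarityReport:
    """Percent of reference residues with a similar target residue.

    ``region`` names a DomainMap region (requires ``domain_map``); None
    means the full reference length. ``columns`` overrides the region
    resolution with an explicit column set.
    """
    ref = aln.row(reference_id)
    tgt = aln.row(target_id)
    if columns is not None:
        cols = list(columns)
        region_name = region or "CUSTOM"
    elif region is None:
        cols = range(aln.n_cols)
        region_name = "FULL"
    else:
        if domain_map is None:
            raise ValidationError("a named region requires a domain_map")
        if region in ("L1", "L2", "L3"):
            interval = domain_map.linker(region)
        elif region in domain_map.regions:
            interval = domain_map.regions[region]
        else:
            raise ValidationError(f"region {region!r} not in domain map")
        cols = _region_columns(aln, reference_id, interval)
        region_name = region

    denom = 0
    similar = 0
    for c in cols:
        if ref[c] == GAP:
            continue
        denom += 1
        if _is_similar(ref[c], tgt[c], matrix, min_score):
            similar += 1
    percent = float(100 * Fraction(similar, denom)) if denom else 0.0
    return SimilarityReport(
        reference_id=reference_id,
        target_id=target_id,
        region=region_name,
        similar_count=similar,
        reference_length_in_region=denom,
        percent=percent,
    )


def domain_similarity_table(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    reference_id: str,
    domain_map: DomainMap,
    exclude_linkers_from: Optional[Dict[str, Tuple[str, ...]]] = None,
    min_score: int = 1,
) -> pd.DataFrame:
    """Per-species similarity for FULL and each domain, reference-relative.

    By default the TRBD column set excludes its internal linkers L2 and L3,
    mirroring how the domain is compared across species. Rows follow
    alignment order; one row per (species, region).
    """
    if exclude_linkers_from is None:
        exclude_linkers_from = {"TRBD": ("L2", "L3")}
    regions = ["FULL"] + [d for d in ("TEN", "TRBD", "RT", "CT") if d in domain_map.regions]
    region_cols: Dict[str, Optional[List[int]]] = {"FULL": None}
    for name in regions[1:]:
        cols = _region_columns(aln, reference_id, domain_map.regions[name])
        for linker in exclude_linkers_from.get(name, ()):  # drop linker bands
            drop = set(_linker_band(aln, reference_id, domain_map, linker))
            cols = [c for c in cols if c not in drop]
        region_cols[name] = cols

    rows = []
    for sp in aln.ids:
        if sp == reference_id:
            continue
        for name in regions:
            rep = pairwise_similarity(
                aln,
                matrix,
                reference_id,
                sp,
                region=name if name != "FULL" else None,
                domain_map=domain_map,
                min_score=min_score,
                columns=region_cols[name],
            )
            rows.append(
                {
                    "reference_id": reference_id,
                    "target_id": sp,
                    "region": name,
                    "similar_count": rep.similar_count,
                    "reference_length_in_region": rep.reference_length_in_region,
                    "percent": round(rep.percent, 1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linkers
# ---------------------------------------------------------------------------


def _linker_band(
    aln: Alignment, reference_id: str, domain_map: DomainMap, linker: str
) -> List[int]:
    """Alignment columns of a linker: strictly between its flanking residues."""
    s, e = domain_map.linker(linker)
    return _band_between(aln, reference_id, s - 1, e)


def extract_linker_lengths(
    aln: Alignment, domain_map: DomainMap
) -> List[LinkerProfile]:
    """Per-species L1/L2/L3 residue counts and cumulative percent vs reference.

    A species' linker length is its number of non-gap residues in the
    columns the linker spans (columns strictly between the flanking
    motif/domain residues of the reference); 'X' counts as a residue.
    """
    if domain_map.reference_id not in aln.rows:
        raise ValidationError(
            f"domain-map reference {domain_map.reference_id!r} not in alignment"
        )
    bands = {
        k: _linker_band(aln, domain_map.reference_id, domain_map, k)
        for k in ("L1", "L2", "L3")
    }
    ref_lengths = {k: e - s for k, (s, e) in domain_map.linkers().items()}
    ref_cum = sum(ref_lengths.values())

    profiles = []
    for sp in aln.ids:
        row = aln.rows[sp]
        counts = {
            k: sum(1 for c in cols if row[c] != GAP) for k, cols in bands.items()
        }
        if all(v == 0 for v in counts.values()) and sp != domain_map.reference_id:
            log.warning("species %s: all linker regions gapped (length 0)", sp)
        cum = sum(counts.values())
        percent = float(100 * Fraction(cum, ref_cum)) if ref_cum else 0.0
        profiles.append(
            LinkerProfile(
                species_id=sp,
                l1=counts["L1"],
                l2=counts["L2"],
                l3=counts["L3"],
                cumulative=cum,
                percent_of_reference=percent,
                linker_class=classify_linker(percent),
            )
        )
    return profiles


def classify_linker(percent: float) -> LinkerClass:
    """Three-way class: SHORT < 60 <= MEDIUM < 100 <= LONG (percent of reference)."""
    if percent < 0:
        raise ValidationError(f"negative linker percent {percent}")
    if percent > OBSERVED_MAX:
        log.info(
            "linker percent %.1f exceeds the observed comparative maximum %.0f",
            percent,
            OBSERVED_MAX,
        )
    if percent < SHORT_BELOW:
        return LinkerClass.SHORT
    if percent < LONG_FROM:
        return LinkerClass.MEDIUM
    return LinkerClass.LONG


def linker_report(profiles: Iterable[LinkerProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": p.species_id,
                "l1": p.l1,
                "l2": p.l2,
                "l3": p.l3,
                "cumulative": p.cumulative,
                "percent_of_reference": round(p.percent_of_reference, 1),
                "linker_class": p.linker_class.value,
            }
            for p in profiles
        ]
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def distance_matrix(
    aln: Alignment, matrix: SubstitutionMatrix, min_score: int = 1
) -> Tuple[List[str], np.ndarray]:
    """Pairwise dissimilarity: 1 − similar / both-ungapped columns.

    Symmetric with a zero diagonal; pairs with no jointly ungapped column
    get distance 1.
    """
    ids = list(aln.ids)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[ids[i]], aln.rows[ids[j]]
            both = similar = 0
            for x, y in zip(a, b):
                if x == GAP or y == GAP:
                    continue
                both += 1
                if _is_similar(x, y, matrix, min_score):
                    similar += 1
            d[i, j] = d[j, i] = 1.0 - similar / both if both else 1.0
    return ids, d
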