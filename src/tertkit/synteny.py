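"""Shared-synteny analysis over ortholog tables.

Given reference genes in chromosome order and their ortholog assignments
in a target species, this module counts orthology coverage of a segment,
tallies orthologs per target chromosome, and detects synteny blocks:
maximal runs of reference-order-consecutive genes whose orthologs share a
target chromosome, tolerating a bounded number of interior genes that are
unmapped or assigned elsewhere.

Orthology is taken as given in the input table; genes with an ortholog
but no chromosome assignment count toward coverage but never join blocks.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import pandas as pd

from .core import (
    OrthologTable,
    SyntenyBlock,
    ValidationError,
    natural_sort_key,
)


def _segment_rows(
    table: OrthologTable, segment: Optional[Tuple[str, int, int]]
) -> pd.DataFrame:
    df = table.df
    if segment is None:
        return df
    chrom, start, end = segment
    return df[
        (df["ref_chrom"] == chrom) & (df["ref_start"] >= start) & (df["ref_start"] < end)
    ]


def coverage_summary(
    table: OrthologTable, segment: Optional[Tuple[str, int, int]] = None
) -> dict:
    """Orthology coverage of a reference segment.

    Returns keys ``n_ref_genes``, ``n_with_ortholog``, ``n_mapped``,
    ``fraction_mapped`` (= mapped / with-ortholog) and
    ``fraction_mapped_defined`` (False when there are no orthologs, in
    which case the fraction is reported as 0).
    """
    rows = _segment_rows(table, segment)
    n_ref = len(rows)
    n_orth = int(rows["target_gene_id"].notna().sum())
    n_mapped = int(rows["target_chrom"].notna().sum())
    defined = n_orth > 0
    return {
        "n_ref_genes": n_ref,
        "n_with_ortholog": n_orth,
        "n_mapped": n_mapped,
        "fraction_mapped": n_mapped / n_orth if defined else 0.0,
        "fraction_mapped_defined": defined,
    }


def count_by_target_chromosome(
    table: OrthologTable, segment: Optional[Tuple[str, int, int]] = None
) -> Dict[str, int]:
    """Mapped-ortholog counts per target chromosome, natural-sorted."""
    rows = _segment_rows(table, segment)
    counts = rows["target_chrom"].dropna().value_counts()
    return {
        chrom: int(counts[chrom])
        for chrom in sorted(counts.index, key=natural_sort_key)
    }


def detect_blocks(
    table: OrthologTable,
    min_block_size: int = 3,
    max_gap: int = 1,
    segment: Optional[Tuple[str, int, int]] = None,
) -> List[SyntenyBlock]:
    """Maximal shared-synteny runs per target chromosome.

    For each target chromosome, its mapped genes are taken in reference
    order; a run breaks wherever more than ``max_gap`` interior genes
    (unmapped or assigned elsewhere) separate two consecutive members.
    Runs shorter than ``min_block_size`` are dropped. Blocks are reported
    ordered by (ref_chrom, span start).
    """
    if min_block_size < 2:
        raise ValidationError("min_block_size must be >= 2")
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    rows = _segment_rows(table, segment)
    blocks: List[SyntenyBlock] = []
    for ref_chrom, sub in rows.groupby("ref_chrom", sort=True):
        sub = sub.sort_values("ref_start", kind="stable").reset_index(drop=True)
        chroms = sub["target_chrom"]
        for c in sorted(chroms.dropna().unique(), key=natural_sort_key):
            idx = [int(i) for i in sub.index[chroms == c]]
            run = [idx[0]]
            for k in idx[1:]:
                if k - run[-1] - 1 <= max_gap:
                    run.append(k)
                else:
                    blocks.extend(_make_block(sub, c, run, min_block_size))
                    run = [k]
            blocks.extend(_make_block(sub, c, run, min_block_size))
    blocks.sort(key=lambda b: (b.span[0], natural_sort_key(b.target_chrom)))
    return blocks


def _make_block(sub: pd.DataFrame, chrom: str, run: List[int], min_size: int):
    if len(run) < min_size:
        return []
    genes = tuple(sub.loc[run, "ref_gene_id"])
    starts = sub.loc[run, "ref_start"]
    n_interrupting = (run[-1] - run[0] + 1) - len(run)
    return [
        SyntenyBlock(
            target_chrom=str(chrom),
            ref_gene_ids=genes,
            span=(int(starts.iloc[0]), int(starts.iloc[-1])),
            n_genes=len(run),
            n_interrupting=n_interrupting,
        )
    ]


def block_report(blocks: List[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_chrom": b.target_chrom,
                "n_genes": b.n_genes,
                "n_interrupting": b.n_interrupting,
                "span_start": b.span[0],
                "span_end": b.span[1],
                "ref_gene_ids": ",".join(b.ref_gene_ids),
            }
            for b in blocks
        ]
    )
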