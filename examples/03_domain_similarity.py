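"""Column filtering and reference-relative domain similarity.

Simulates a family, strips every alignment column containing a gap or an
X (gap tolerance 0%), and computes BLOSUM62 similarity percentages per
domain relative to the reference protein: a reference residue counts as
similar when the aligned residue scores > 0 against it. The TRBD figures
exclude the domain's internal linkers L2 and L3.
"""

from tertkit import load_builtin_matrix
from tertkit.alnstats import domain_similarity_table, filter_columns
from tertkit.simulate import FamilyProfile, simulate_tert_family

family = simulate_tert_family(
    FamilyProfile(
        n_species=4,
        linker_lengths=[(150, 100, 50), (120, 80, 40), (60, 40, 20), (30, 20, 10)],
        domain_sub_rate=0.15,
        seed=7,
    )
)
aln = family.alignment

filtered, kept = filter_columns(aln, gap_tolerance=0.0, treat_x_as_gap=True)
print(f"gap/X filtering at 0% tolerance: {aln.n_cols} -> {filtered.n_cols} columns")
print("(variable-length linkers produce gap columns, which are removed)\n")

matrix = load_builtin_matrix("BLOSUM62")
table = domain_similarity_table(aln, matrix, "ref", family.domain_map)
print(table.to_string(index=False))
print(
    "\npercent = similar residues / reference residues in the region;"
    "\nat a 15% per-site substitution rate most domain residues remain similar."
)
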