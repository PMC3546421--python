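"""Linker-length profiles across a simulated TERT-like protein family.

Simulates five species whose three inter-domain linkers (L1 between TEN
and TRBD; L2 and L3 inside the TRBD) are planted at known lengths, then
reads those lengths back from the true alignment. The cumulative length
as a percentage of the reference species defines the three classes:
LONG (>=100%), MEDIUM (60-99%), SHORT (<60%).
"""

from tertkit.alnstats import extract_linker_lengths, linker_report
from tertkit.simulate import FamilyProfile, simulate_tert_family

profile = FamilyProfile(
    n_species=5,
    linker_lengths=[
        (150, 100, 50),  # reference: 300 residues cumulative
        (160, 110, 60),  # longer than reference -> LONG
        (120, 90, 90),   # same cumulative -> LONG
        (90, 60, 30),    # 60% -> MEDIUM (boundary)
        (30, 20, 10),    # 20% -> SHORT
    ],
    species_ids=["ref", "spA", "spB", "spC", "spD"],
    seed=42,
)
family = simulate_tert_family(profile)
profiles = extract_linker_lengths(family.alignment, family.domain_map)
print(linker_report(profiles).to_string(index=False))
print(
    "\nEach row: per-linker residue counts, their sum, that sum as a percent"
    "\nof the reference species, and the resulting class."
)
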