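"""Classify the seven alternative-splicing variants of the worked example.

Builds the packaged 16-exon TERT-like gene model (4522-nt transcript,
3891-nt ORF) and its seven splice events, derives each single-event
transcript, and prints the reading-frame verdict. A variant is RETAINED
when translation still ends at the original stop codon and PTC when a
premature stop appears upstream — the signature of an NMD target.
"""

from tertkit import build_platypus_fixture
from tertkit.splicing import classify_orf, derive_transcript, enumerate_combinations

model, events = build_platypus_fixture()

wt = derive_transcript(model, [])
wt_call = classify_orf(model, wt)
print(f"wild type: {wt.length} nt transcript, {wt_call.protein_length} aa protein\n")

print(f"{'variant':8} {'status':10} {'frame':>5} {'length (nt)':>12} {'protein (aa)':>13}")
for name, ev in sorted(events.items()):
    tr = derive_transcript(model, [ev])
    call = classify_orf(model, tr, nmd_rule=50)
    print(
        f"{name:8} {call.status.value:10} {call.net_frame_shift:>5}"
        f" {tr.length:>12} {call.protein_length:>13}"
    )

print("\npairwise combinations (footprint disjointness):")
for c in enumerate_combinations(model, list(events.values()), 2):
    if len(c.event_ids) == 2:
        verdict = "compatible" if c.valid else "mutually exclusive"
        print(f"  {'+'.join(c.event_ids):8} {verdict}")
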