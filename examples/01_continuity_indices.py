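"""Continuity indices on two visit profiles the UPC cannot distinguish.

Patient A made five visits to one GP and one visit to each of five other
GPs; patient B made ten visits split equally across two GPs. Both see
their most frequent GP in half their visits (UPC 0.5), but B's care is
far more concentrated overall, which only the COC index picks up.
"""

from gpcontinuity import coc_from_counts, upc_from_counts

profiles = {
    "A: 5 visits to one GP + 1 visit to each of 5 others": (5, 1, 1, 1, 1, 1),
    "B: 10 visits split across two GPs": (5, 5),
}

for label, counts in profiles.items():
    print(label)
    print(f"  UPC = {upc_from_counts(counts):.2f}   "
          f"COC = {coc_from_counts(counts):.2f}")

print(
    "\nSame UPC, different COC: the COC index is the share of visit pairs "
    "made\nto the same GP, so spreading the remaining visits over five GPs "
    "halves it."
)
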