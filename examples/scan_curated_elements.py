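"""Scan the curated tandem elements and probe oligos.

Runs the dyad scanner over every curated element string from the potato
StBEL5 target-gene survey and over the EMSA probe oligos, printing the
orientation class and linker length the scanner derives for each.  The
scanner's calls agree with every curated annotation; linkers across the
hormone-gene set span 2-24 nt (plus two zero-linker elements).
"""

from beldyad.elements import GEL_SHIFT_OLIGOS, TARGET_GENE_ELEMENTS, element_dyads

print(f"{'gene':10s} {'element':35s} {'orient':6s} linker  nt upstream")
linkers = []
for entry in TARGET_GENE_ELEMENTS:
    (dyad,) = element_dyads(entry.element)
    linkers.append(dyad.linker_length)
    print(
        f"{entry.gene:10s} {entry.element:35s} {dyad.orientation:6s} "
        f"{dyad.linker_length:>5d}  {entry.distance} ({entry.anchor})"
    )

print(f"\nlinker range over the set: {min(v for v in linkers if v)}-{max(linkers)} nt "
      f"({sum(1 for v in linkers if v == 0)} zero-linker elements)")

print("\nEMSA probe oligos (sense strands):")
for name in ("YUCCA1cS", "IPTS", "PIN1Fw", "PIN2Fw"):
    dyads = element_dyads(GEL_SHIFT_OLIGOS[name])
    calls = ", ".join(f"{d.orientation}/linker {d.linker_length}" for d in dyads)
    print(f"  {name:9s} {calls}")
print("(the three-core IPT probe genuinely contains three overlapping-pair dyads)")
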