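"""Build an ideal B-DNA duplex and measure its minor-groove profile.

The 23-bp operator sequence is built as regular fiber B-DNA (36 deg
twist, 3.38 Å rise, zero roll) and the cross-strand phosphate P-to-P
distances across the minor groove are profiled.  For regular B-DNA the
interior minima average 11.7 Å — the reference against which groove
narrowing in protein-bound operators is measured.
"""

import helixread as hx

sequence = "AACACGAATATCATCTACCAATT"
duplex = hx.build_fiber_bdna(sequence)
print(f"built {len(sequence)}-bp duplex: {duplex.n_atoms} heavy atoms, "
      f"chains {[c.cid for c in duplex.chains]}")

pairs = hx.detect_base_pairs(duplex)
print(f"detected {len(pairs)} base pairs, "
      f"all Watson-Crick: {all(p.pair_type == 'watson-crick' for p in pairs)}")

profile = hx.groove_profile(duplex)
mean = profile.mean_minor()
dmin, where = profile.min_minor()
print(f"mean minimal minor-groove P-P (interior): {mean:.2f} A")
print(f"narrowest point: {dmin:.2f} A at {where.chain}:{where.number}")
print("a bound transcription factor would compress parts of this profile by 1-2 A;")
print("deviations from the 11.7 A reference are the shape signal proteins read out")
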