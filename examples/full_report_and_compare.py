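"""Run the whole pipeline on two duplexes and compare their shapes.

A straight duplex and a uniformly bent one (3 deg roll per step) are
analysed end to end — torsions and backbone states, base-pair and step
parameters, groove profile — and the comparative tables show the roll
difference and its (small) effect on the groove profile.
"""

import helixread as hx

sequence = "AACACGAATATCATCTACCAATT"
straight = hx.build_fiber_bdna(sequence)
bent = hx.build_fiber_bdna(sequence, hx.FiberParams(roll=3.0))

cfg = hx.AnalysisConfig(center=("C", 12))
rep_straight = hx.analyze_complex(straight, cfg)
rep_bent = hx.analyze_complex(bent, cfg)
rep_bent.structure_id = "bent-3deg"

print("straight duplex backbone census:", rep_straight.state_counts)
print("step parameters (first 3 rows):")
print(rep_straight.step_table.head(3).to_string(index=False))

tables = hx.compare_complexes([rep_straight, rep_bent])
print("\nper-complex summary:")
print(tables["summary"].round(3).to_string())
print("\nmean roll differs by the generator's 3 deg; a sustained roll of a")
print("few degrees is what curves operator DNA around a regulatory helix")
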