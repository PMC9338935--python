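"""Flip phosphodiester backbone states and classify them.

B-DNA phosphates populate two substates distinguished by the
epsilon - zeta torsion difference: B_I near -90 deg and B_II near
+90 deg.  Here four nucleotides of an ideal (all-B_I) duplex are driven
into B_II by local phosphate repositioning, mimicking the mixed-state
backbone seen in bound operators, and the classifier census confirms
the flip.
"""

from collections import Counter

import helixread as hx
from helixread.dna import backbone_torsions, classify_backbone_state, nucleotides_of

duplex = hx.build_fiber_bdna("AACACGAATATCATCTACCAATT")


def census(model):
    return Counter(classify_backbone_state(backbone_torsions(n)).state
                   for n in nucleotides_of(model))


print("ideal fiber duplex:", dict(census(duplex)))

targets = {("C", 10): {"epsilon": -100.0, "zeta": 170.0},
           ("C", 12): {"epsilon": -100.0, "zeta": 170.0},
           ("D", 10): {"epsilon": -100.0, "zeta": 170.0},
           ("D", 12): {"epsilon": -100.0, "zeta": 170.0}}
flipped = hx.apply_step_perturbations(duplex, backbone_overrides=targets)
print("after four epsilon/zeta overrides:", dict(census(flipped)))
print("the 44 classifiable phosphates (5'-termini excluded) now show a")
print("4-B_II / 40-B_I mix; eps - zeta = +90 deg is the B_II signature")
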