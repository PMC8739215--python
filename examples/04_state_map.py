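"""Map activity types over the two intracortical EI couplings.

Classifies the settled activity on a coarse (c_py_ei, c_i1_ei) grid at
fixed thalamus-to-EI coupling and prints a character map plus label
counts.  The bands run diagonally: normal background at weak inhibition /
strong excitation, then preictal, clonic, absence and slow-rhythmic
strips, with the tonic region filling the rest of the plane.
"""

import numpy as np

from tcnmm import ModelParameters, map_2d

SYMBOL = {"normal": ".", "preictal": "p", "slow_rhythmic": "s",
          "typical_absence": "T", "atypical_absence": "Y", "clonic": "c",
          "tonic": "R", "unclassified": "?"}

params = ModelParameters()
state_map = map_2d(params, np.linspace(0.1, 0.9, 20),
                   np.linspace(0.2, 0.9, 20), c_tc_ei=4.5)

print("rows: c_py_ei 0.1 -> 0.9; cols: c_i1_ei 0.2 -> 0.9")
for row in state_map.labels:
    print("  " + "".join(SYMBOL[lab.value] for lab in row))
for lab, n in state_map.label_counts().items():
    if n:
        print(f"{lab.value:18s} {n:4d} cells")
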