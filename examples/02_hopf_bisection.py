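"""Localize the Hopf bifurcation that marks seizure onset.

Tracks the resting equilibrium of the constant-input circuit while the
GABAergic coupling from fast inhibitory interneurons onto excitatory
interneurons (c_i1_ei) increases, and bisects the parameter value where
the leading complex eigenvalue pair of the Jacobian crosses zero real
part.  Below the crossing the equilibrium is a stable focus (normal
background activity); above it a small limit cycle is born and grows —
the preictal transition.
"""

import numpy as np

from tcnmm import (DriveSpec, EquilibriumTracker, ModelParameters,
                   locate_hopf)

params = ModelParameters()  # c_py_ei = 0.8, c_tc_ei = 4.5

hopf = locate_hopf(params, "c_i1_ei", (0.2, 0.45))
print(f"Hopf crossing at c_i1_ei = {hopf:.4f}")

tracker = EquilibriumTracker(params, "c_i1_ei", DriveSpec())
for value in (hopf - 0.01, hopf + 0.01):
    rec = tracker.at(value)
    lead = rec.eigenvalues[np.abs(rec.eigenvalues.imag) > 1e-9]
    print(f"  c_i1_ei={value:.4f}: leading pair real part "
          f"{lead.real.max():+.3f}  ({rec.stability})")
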