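"""Bifurcation sweep with period-doubling and bistability detection.

Sweeps c_i1_ei upward and downward with attractor inheritance (each run
seeded by the previous final state), prints where the distinct local-
maximum level count doubles (period doubling -> the two-amplitude
preictal spike pattern) and where forward and backward sweeps settle
onto different attractors (hysteresis window bounded by fold-limit-cycle
/ subcritical-Hopf points, where two spike-and-wave patterns coexist).
"""

import numpy as np

from tcnmm import (ModelParameters, detect_bistable_windows,
                   detect_period_doubling, sweep_1d)

params = ModelParameters()

grid = np.arange(0.34, 0.4001, 0.001)
diag = sweep_1d(params, "c_i1_ei", grid)
print("period-doubling events:",
      [f"{x:.4f}" for x in detect_period_doubling(diag)])

grid2 = np.arange(0.40, 0.5501, 0.002)
fwd = sweep_1d(params, "c_i1_ei", grid2)
bwd = sweep_1d(params, "c_i1_ei", grid2[::-1])
for lo, hi in detect_bistable_windows(fwd, bwd):
    print(f"bistable window: [{lo:.3f}, {hi:.3f}]")
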