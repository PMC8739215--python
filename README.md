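# tcnmm — thalamocortical neural mass model with excitatory interneurons

A toolkit for studying seizure-onset dynamics in a six-population neural
mass model of the thalamocortical loop.  The circuit couples cortical
pyramidal cells (PY), fast and slow inhibitory interneurons (I1, I2),
excitatory interneurons / spiny stellate cells (EI), the thalamic relay
nucleus (TC) and the reticular nucleus (RE):

    dPY/dt = tau_1 (h_py − PY + c_py_py f(PY) − c_i1_py f(I1)
                    + c_tc_py f(TC) − c_i2_py f(I2) + c_ei_py f(EI)) + N_py
    dI1/dt = tau_2 (h_i1 − I1 + c_py_i1 f(PY) − c_i2_i1 f(I2)
                    + c_tc_i1 f(TC) + c_ei_i1 f(EI))
    dI2/dt = tau_3 (h_i2 − I2 + c_py_i2 f(PY) − c_i1_i2 f(I1) + c_tc_i2 f(TC))
    dEI/dt = tau_4 (h_ei − EI + c_py_ei f(PY) − c_i1_ei f(I1) + c_tc_ei f(TC))
    dTC/dt = tau_5 (h_tc − TC + c_py_tc f(PY) − c_re_tc f(RE)) + N_tc
    dRE/dt = tau_6 (h_re − RE + c_py_re f(PY) − c_re_re f(RE) + c_tc_re f(TC))

with the sigmoid transfer f(x) = 1/(1 + ε^(−x)), ε = 2.5·10^5, drives
N = B + a·sin(2πft) on the cortical and sensory channels, and model
output (PY + I1 + I2 + EI)/4.  Depending on the EI coupling strengths
the output reproduces seven activity types seen in epilepsy — normal
background, preictal spikes, slow rhythmic activity, typical and
atypical absence (spike-and-wave), clonic and tonic discharges — and the
toolkit localizes the bifurcations that separate them.

It is intended for computational-neuroscience work on interictal→ictal
transitions: what the package computes are bifurcation diagrams
(eigenvalue-based Hopf bisection plus waveform-based period-doubling and
hysteresis localization), 2D activity maps over coupling planes, and
driven frequency-response curves with resonance and amplitude-jump
detection.

## Worked example

```python
import numpy as np
from tcnmm import (ModelParameters, classify_state, compute_features,
                   locate_hopf, simulate, sweep_1d, detect_period_doubling)

params = ModelParameters()            # resting circuit, c_i1_ei = 0.3
feats  = compute_features(simulate(params))
print(classify_state(feats).value, feats.DF)

hopf = locate_hopf(params, "c_i1_ei", (0.2, 0.45))
print(f"seizure onset (Hopf) at c_i1_ei = {hopf:.4f}")

diag = sweep_1d(params, "c_i1_ei", np.arange(0.34, 0.4001, 0.001))
print(f"first period doubling: {detect_period_doubling(diag)[0]:.4f}")
```

prints

```
normal 0.0
seizure onset (Hopf) at c_i1_ei = 0.3491
first period doubling: 0.3555
```

meaning: at the default couplings the cortical output settles to a fixed
point (normal background, dominant frequency 0); strengthening the
GABAergic input onto the excitatory interneurons destabilizes that
equilibrium through a supercritical Hopf bifurcation at c_i1_ei ≈ 0.349
(birth of the low-amplitude preictal oscillation), and at ≈ 0.356 the
cycle period-doubles into the two-amplitude preictal spike pattern that
precedes the clonic discharge.

The `examples/` directory holds one short narrative script per
capability (simulation + classification, Hopf bisection, bifurcation
sweeps with bistability, 2D state maps, frequency response with jump
detection, and the state-switch protocol); each prints the numbers it
computes and what they mean.  A thin CLI mirrors the library
(`tcnmm simulate`, `sweep1d`, `map2d`, `freqresp`, `classify`,
`fixtures`).

The scientific background, parameter meanings, numerical choices and
known limitations are documented in `docs/methods.md`.

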