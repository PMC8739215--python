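"""Seizure onset and offset driven by a parameter schedule.

Holds a 1 Hz cortical drive fixed while c_py_ei steps 0.76 -> 0.748 ->
0.76 (normal -> preictal -> normal).  During the middle epoch the same
weak drive evokes a several-fold larger absence-like response with two
distinct trough levels; when the coupling recovers, so does the output.
The circuit's response to an unchanged stimulus is thus controlled by
its internal state.
"""

from tcnmm import ModelParameters, state_switch_protocol

params = ModelParameters(c_i1_ei=0.3, c_tc_ei=4.5)
result = state_switch_protocol(params)  # default 20 s epochs, fpy = 1 Hz

for (t0, t1, value), f in zip(result.epochs, result.epoch_features):
    trough_spread = f.Pmin1 - f.Pmin2
    print(f"t in [{t0:4.0f},{t1:4.0f}] s  c_py_ei={value:.3f}  "
          f"ptp={f.ptp:.4f}  DF={f.DF:.2f} Hz  "
          f"trough spread={trough_spread:.4f}")
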