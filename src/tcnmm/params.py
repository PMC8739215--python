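"""Model parameters and input drives for the thalamocortical circuit.

The model couples six neural populations: cortical pyramidal cells (PY),
fast (GABA_A) and slow (GABA_B) inhibitory interneurons (I1, I2), excitatory
interneurons / spiny stellate cells (EI), thalamic relay nucleus (TC) and
thalamic reticular nucleus (RE).  Coupling strengths follow the naming
convention ``c_SOURCE_TARGET``: the coefficient multiplying the firing rate
of SOURCE inside TARGET's equation.  ``h_*`` are constant input offsets,
``tau_1..tau_6`` time-scale factors (1/s) and ``epsilon`` the steepness base
of the logistic firing-rate transfer function f(x) = 1/(1 + epsilon**(-x)).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelParameters", "DriveSpec", "PARAM_KEYS"]


# Flat layout of the parameter vector consumed by the compiled RK4 kernel.
# Order matters; keep in sync with model._field.
_VEC_KEYS = (
    "c_py_py", "c_py_i1", "c_i1_py", "c_re_re", "c_tc_re", "c_re_tc",
    "c_py_tc", "c_py_re", "c_tc_py", "c_py_i2", "c_tc_i1", "c_tc_i2",
    "c_ei_i1", "c_ei_py", "c_i2_py", "c_i2_i1", "c_i1_i2",
    "c_py_ei", "c_i1_ei", "c_tc_ei", "c_Npy_py", "c_Ntc_tc",
    "tau_1", "tau_2", "tau_3", "tau_4", "tau_5", "tau_6",
    "h_py", "h_i1", "h_i2", "h_ei", "h_tc", "h_re",
)


@dataclass
class ModelParameters:
    """Connectivity strengths, input offsets and time scales of the circuit.

    Defaults reproduce the reference parameterization of the circuit.
    """

    # cortical couplings
    c_py_py: float = 1.89
    c_py_i1: float = 4.0
    c_i1_py: float = 1.8
    c_py_i2: float = 1.5
    c_i2_py: float = 0.05
    c_i2_i1: float = 0.1
    c_i1_i2: float = 0.5
    # thalamic couplings
    c_re_re: float = 0.01
    c_tc_re: float = 10.0
    c_re_tc: float = 1.4
    c_py_tc: float = 3.0
    c_py_re: float = 1.4
    c_tc_py: float = 1.0
    c_tc_i1: float = 0.05
    c_tc_i2: float = 0.05
    # excitatory-interneuron couplings
    c_ei_py: float = 0.442
    c_ei_i1: float = 0.05
    c_py_ei: float = 0.8
    c_i1_ei: float = 0.3
    c_tc_ei: float = 4.5
    # input gains (multiply the whole external drive; default 1 leaves
    # the equations in model.py unchanged)
    c_Npy_py: float = 1.0
    c_Ntc_tc: float = 1.0
    # time scales (1/s)
    tau_1: float = 21.5
    tau_2: float = 31.5
    tau_3: float = 0.1
    tau_4: float = 4.5
    tau_5: float = 3.8
    tau_6: float = 3.9
    # constant input offsets
    h_py: float = -0.4
    h_i1: float = -3.4
    h_i2: float = -2.0
    h_ei: float = -1.0
    h_tc: float = -2.5
    h_re: float = -3.2
    # transfer-function steepness base
    epsilon: float = 250000.0
    # EI-ablation variant: when False the EI population is frozen at zero,
    # every coupling with EI as source or target is dropped, and the model
    # output averages the remaining three cortical populations.
    ei_enabled: bool = True

    def __post_init__(self) -> None:
        for k in ("tau_1", "tau_2", "tau_3", "tau_4", "tau_5", "tau_6"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be > 0, got {getattr(self, k)}")
        if self.epsilon <= 1:
            raise ValueError(f"epsilon must be > 1, got {self.epsilon}")
        for k in _VEC_KEYS:
            if k.startswith("c_") and getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0, got {getattr(self, k)}")

    # -- derived quantities -------------------------------------------------

    @property
    def log_epsilon(self) -> float:
        return math.log(self.epsilon)

    def to_vector(self) -> np.ndarray:
        """Flat float64 vector for the compiled kernel (couplings, taus,
        offsets, log(epsilon), EI flag)."""
        v = np.empty(len(_VEC_KEYS) + 2)
        for i, k in enumerate(_VEC_KEYS):
            v[i] = getattr(self, k)
        v[-2] = self.log_epsilon
        v[-1] = 1.0 if self.ei_enabled else 0.0
        return v

    # -- convenience --------------------------------------------------------

    def replace(self, **overrides) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=1))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d or {})


PARAM_KEYS = tuple(f.name for f in dataclasses.fields(ModelParameters))


@dataclass
class DriveSpec:
    """External inputs: biased sinusoids to PY (cortical) and TC (sensory).

    N_py = B_Npy + a_py sin(2 pi fpy t),  N_tc = B_Ntc + a_tc sin(2 pi ftc t).
    Constant-input mode (used for all autonomous bifurcation analysis) is
    a_py = a_tc = 0.
    """

    B_Npy: float = 0.7
    a_py: float = 0.0
    fpy: float = 1.0
    B_Ntc: float = 0.1
    a_tc: float = 0.0
    ftc: float = 1.0

    def __post_init__(self) -> None:
        if self.a_py < 0 or self.a_tc < 0:
            raise ValueError("drive amplitudes must be >= 0")
        if self.fpy < 0 or self.ftc < 0:
            raise ValueError("drive frequencies must be >= 0")

    @property
    def is_constant(self) -> bool:
        return self.a_py == 0.0 and self.a_tc == 0.0

    def replace(self, **overrides) -> "DriveSpec":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DriveSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown drive keys: {sorted(unknown)}")
        return cls(**d)
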