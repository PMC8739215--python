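"""Vector field and fixed-step RK4 simulator for the six-population model.

State order everywhere: (PY, I1, I2, EI, TC, RE).

The right-hand sides (constant-input form, drives N_py/N_tc added outside
the tau multiplier):

    dPY/dt = tau_1 (h_py - PY + c_py_py f(PY) - c_i1_py f(I1)
                    + c_tc_py f(TC) - c_i2_py f(I2) + c_ei_py f(EI)) + N_py
    dI1/dt = tau_2 (h_i1 - I1 + c_py_i1 f(PY) - c_i2_i1 f(I2)
                    + c_tc_i1 f(TC) + c_ei_i1 f(EI))
    dI2/dt = tau_3 (h_i2 - I2 + c_py_i2 f(PY) - c_i1_i2 f(I1) + c_tc_i2 f(TC))
    dEI/dt = tau_4 (h_ei - EI + c_py_ei f(PY) - c_i1_ei f(I1) + c_tc_ei f(TC))
    dTC/dt = tau_5 (h_tc - TC + c_py_tc f(PY) - c_re_tc f(RE)) + N_tc
    dRE/dt = tau_6 (h_re - RE + c_py_re f(PY) - c_re_re f(RE) + c_tc_re f(TC))

with f(x) = 1/(1 + epsilon**(-x)).  The model output is the mean of the
four cortical populations, (PY + I1 + I2 + EI)/4 (three when the EI
population is ablated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
import pandas as pd
from scipy.special import expit

from .params import DriveSpec, ModelParameters

__all__ = [
    "sigmoid", "sigmoid_derivative", "drive_value", "vector_field",
    "simulate", "SimulationResult", "SimulationDiverged", "InvalidState",
    "STATE_NAMES", "DEFAULT_DT", "DEFAULT_DURATION", "DIVERGENCE_LIMIT",
]

STATE_NAMES = ("PY", "I1", "I2", "EI", "TC", "RE")
DEFAULT_DT = 0.0039          # seconds
DEFAULT_DURATION = 60.0      # seconds
DIVERGENCE_LIMIT = 1e6       # model units


class InvalidState(ValueError):
    """A non-finite state or input was passed to the model."""


class SimulationDiverged(RuntimeError):
    """Trajectory exceeded the divergence guard."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(
            f"state magnitude exceeded {DIVERGENCE_LIMIT:g} at step "
            f"{step} (t = {time:.4f} s)"
        )


def sigmoid(x, epsilon: float = 250000.0):
    """Logistic transfer function f(x) = 1/(1 + epsilon**(-x)).

    Computed as expit(ln(epsilon) * x) for overflow-free evaluation at
    any finite x.
    """
    if epsilon <= 1:
        raise ValueError("epsilon must be > 1")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidState("non-finite input to sigmoid")
    out = expit(np.log(epsilon) * x)
    return float(out) if out.ndim == 0 else out


def sigmoid_derivative(x, epsilon: float = 250000.0):
    """d/dx of the transfer function: ln(epsilon) * f(x) * (1 - f(x))."""
    s = sigmoid(x, epsilon)
    return np.log(epsilon) * s * (1.0 - s)


def drive_value(spec: DriveSpec, t, p: ModelParameters | None = None):
    """External drives (N_py, N_tc) at time(s) ``t``.

    The input gains c_Npy_py / c_Ntc_tc (default 1) multiply the whole
    biased sinusoid.
    """
    t = np.asarray(t, dtype=float)
    g_py = p.c_Npy_py if p is not None else 1.0
    g_tc = p.c_Ntc_tc if p is not None else 1.0
    npy = g_py * (spec.B_Npy + spec.a_py * np.sin(2 * np.pi * spec.fpy * t))
    ntc = g_tc * (spec.B_Ntc + spec.a_tc * np.sin(2 * np.pi * spec.ftc * t))
    if t.ndim == 0:
        return float(npy), float(ntc)
    return npy, ntc


def vector_field(s, p: ModelParameters, n_py: float, n_tc: float) -> np.ndarray:
    """Right-hand side ds/dt at state ``s`` with external drives n_py, n_tc.

    Reference (uncompiled) implementation; the simulator uses an
    equivalent jitted kernel.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (6,):
        raise ValueError(f"state must have shape (6,), got {s.shape}")
    if not (np.all(np.isfinite(s)) and np.isfinite(n_py) and np.isfinite(n_tc)):
        raise InvalidState("non-finite state or drive")
    PY, I1, I2, EI, TC, RE = s
    f = lambda x: sigmoid(x, p.epsilon)  # noqa: E731
    fPY, fI1, fI2, fTC, fRE = f(PY), f(I1), f(I2), f(TC), f(RE)
    fEI = f(EI) if p.ei_enabled else 0.0
    c_ei_py = p.c_ei_py if p.ei_enabled else 0.0
    c_ei_i1 = p.c_ei_i1 if p.ei_enabled else 0.0
    d = np.empty(6)
    d[0] = p.tau_1 * (p.h_py - PY + p.c_py_py * fPY - p.c_i1_py * fI1
                      + p.c_tc_py * fTC - p.c_i2_py * fI2
                      + c_ei_py * fEI) + n_py
    d[1] = p.tau_2 * (p.h_i1 - I1 + p.c_py_i1 * fPY - p.c_i2_i1 * fI2
                      + p.c_tc_i1 * fTC + c_ei_i1 * fEI)
    d[2] = p.tau_3 * (p.h_i2 - I2 + p.c_py_i2 * fPY - p.c_i1_i2 * fI1
                      + p.c_tc_i2 * fTC)
    if p.ei_enabled:
        d[3] = p.tau_4 * (p.h_ei - EI + p.c_py_ei * fPY - p.c_i1_ei * fI1
                          + p.c_tc_ei * fTC)
    else:
        d[3] = 0.0
    d[4] = p.tau_5 * (p.h_tc - TC + p.c_py_tc * fPY - p.c_re_tc * fRE) + n_tc
    d[5] = p.tau_6 * (p.h_re - RE + p.c_py_re * fPY - p.c_re_re * fRE
                      + p.c_tc_re * fTC)
    return d


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

@nb.njit(cache=True)
def _sig(x, log_eps):
    z = log_eps * x
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


@nb.njit(cache=True)
def _field(s, q, n_py, n_tc, out):
    # q layout: params._VEC_KEYS + (log_eps, ei_flag)
    le = q[34]
    ei_on = q[35] > 0.5
    fPY = _sig(s[0], le)
    fI1 = _sig(s[1], le)
    fI2 = _sig(s[2], le)
    fEI = _sig(s[3], le) if ei_on else 0.0
    fTC = _sig(s[4], le)
    fRE = _sig(s[5], le)
    c_ei_i1 = q[12] if ei_on else 0.0
    c_ei_py = q[13] if ei_on else 0.0
    out[0] = q[22] * (q[28] - s[0] + q[0] * fPY - q[2] * fI1 + q[8] * fTC
                      - q[14] * fI2 + c_ei_py * fEI) + n_py
    out[1] = q[23] * (q[29] - s[1] + q[1] * fPY - q[15] * fI2
                      + q[10] * fTC + c_ei_i1 * fEI)
    out[2] = q[24] * (q[30] - s[2] + q[9] * fPY - q[16] * fI1 + q[11] * fTC)
    out[3] = q[25] * (q[31] - s[3] + q[17] * fPY - q[18] * fI1
                      + q[19] * fTC) if ei_on else 0.0
    out[4] = q[26] * (q[32] - s[4] + q[6] * fPY - q[5] * fRE) + n_tc
    out[5] = q[27] * (q[33] - s[5] + q[7] * fPY - q[3] * fRE + q[4] * fTC)


@nb.njit(cache=True)
def _rk4(q, s0, dt, n_steps, t0, B_Npy, a_py, fpy, B_Ntc, a_tc, ftc, limit):
    traj = np.empty((n_steps + 1, 6))
    traj[0] = s0
    s = s0.copy()
    k1 = np.empty(6); k2 = np.empty(6); k3 = np.empty(6); k4 = np.empty(6)
    tmp = np.empty(6)
    two_pi = 2.0 * np.pi
    g_py = q[20]
    g_tc = q[21]
    for i in range(n_steps):
        t = t0 + i * dt
        th = t + 0.5 * dt
        tf = t + dt
        npy_a = g_py * (B_Npy + a_py * np.sin(two_pi * fpy * t))
        ntc_a = g_tc * (B_Ntc + a_tc * np.sin(two_pi * ftc * t))
        npy_b = g_py * (B_Npy + a_py * np.sin(two_pi * fpy * th))
        ntc_b = g_tc * (B_Ntc + a_tc * np.sin(two_pi * ftc * th))
        npy_c = g_py * (B_Npy + a_py * np.sin(two_pi * fpy * tf))
        ntc_c = g_tc * (B_Ntc + a_tc * np.sin(two_pi * ftc * tf))
        _field(s, q, npy_a, ntc_a, k1)
        for j in range(6):
            tmp[j] = s[j] + 0.5 * dt * k1[j]
        _field(tmp, q, npy_b, ntc_b, k2)
        for j in range(6):
            tmp[j] = s[j] + 0.5 * dt * k2[j]
        _field(tmp, q, npy_b, ntc_b, k3)
        for j in range(6):
            tmp[j] = s[j] + dt * k3[j]
        _field(tmp, q, npy_c, ntc_c, k4)
        for j in range(6):
            s[j] = s[j] + dt * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) / 6.0
        bad = False
        for j in range(6):
            if np.abs(s[j]) > limit or not np.isfinite(s[j]):
                bad = True
        if bad:
            return traj, i + 1, True
        traj[i + 1] = s
    return traj, n_steps, False


# ---------------------------------------------------------------------------
# public simulator
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Fixed-step trajectory plus the cortical-mean output series."""

    dt: float
    times: np.ndarray          # (n+1,) uniform grid starting at t0
    states: np.ndarray         # (n+1, 6) in STATE_NAMES order
    output: np.ndarray         # (n+1,) cortical mean
    params: ModelParameters
    drive: DriveSpec

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t", self.times)
        df["output"] = self.output
        return df

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False,
                               float_format="%.17g")


def cortical_mean(states: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Model output: mean of cortical populations (PY, I1, I2, EI), or
    (PY, I1, I2) under EI ablation."""
    if p.ei_enabled:
        return states[..., :4].mean(axis=-1)
    return states[..., :3].mean(axis=-1)


def simulate(
    p: ModelParameters,
    d: DriveSpec | None = None,
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    s0=None,
    t0: float = 0.0,
    raise_on_divergence: bool = True,
) -> SimulationResult:
    """Integrate the model with classic fixed-step RK4.

    Deterministic: identical arguments give bit-identical output arrays.
    The default initial condition is the zero state.
    """
    if d is None:
        d = DriveSpec()
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    if n_steps < 2:
        raise ValueError("duration/dt must be at least 2")
    if s0 is None:
        s0 = np.zeros(6)
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != (6,) or not np.all(np.isfinite(s0)):
        raise InvalidState("initial state must be 6 finite values")
    q = p.to_vector()
    traj, reached, diverged = _rk4(
        q, s0, dt, n_steps, t0,
        d.B_Npy, d.a_py, d.fpy, d.B_Ntc, d.a_tc, d.ftc,
        DIVERGENCE_LIMIT,
    )
    if diverged and raise_on_divergence:
        raise SimulationDiverged(reached, t0 + reached * dt)
    traj = traj[: reached + 1]
    times = t0 + dt * np.arange(traj.shape[0])
    return SimulationResult(
        dt=dt, times=times, states=traj,
        output=cortical_mean(traj, p), params=p, drive=d,
    )
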