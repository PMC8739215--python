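"""Equilibria, linear stability and Hopf localization for constant inputs.

With constant drives the model is autonomous and its equilibria solve
F(s) = 0 for the six-dimensional vector field.  Because the firing-rate
sigmoid is extremely steep (epsilon = 2.5e5), Newton's method needs
damping, and the physiologically relevant cortical equilibrium branch can
fold: near a fold the branch tracked by warm-started continuation
disappears and must be re-acquired by a deterministic multi-start search.
Saturated-corner equilibria (all populations pinned at their sigmoid
plateaus) coexist with the cortical branch, so branch recovery always
selects the equilibrium closest in state space to the last tracked one.

A Hopf bifurcation is localized by bisection on the real part of the
leading complex-conjugate eigenvalue pair of the tracked equilibrium.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.linalg import LinAlgError, eigvals, norm, solve

from .model import sigmoid_derivative, vector_field
from .params import DriveSpec, ModelParameters

__all__ = [
    "EquilibriumRecord", "jacobian", "find_equilibria", "newton_equilibrium",
    "locate_hopf", "leading_complex_real", "NoCrossingError",
    "BranchLostError", "EquilibriumTracker",
]

RESIDUAL_TOL = 1e-10
DEDUP_TOL = 1e-6


class NoCrossingError(RuntimeError):
    """The tracked eigenvalue real part does not change sign over the bracket."""


class BranchLostError(RuntimeError):
    """The tracked equilibrium branch could not be continued or re-acquired."""


@dataclass
class EquilibriumRecord:
    """One equilibrium with its linearization."""

    state: np.ndarray
    eigenvalues: np.ndarray    # six complex numbers of the Jacobian
    stability: str             # stable_node | stable_focus | unstable | saddle
    residual: float

    @property
    def max_real_part(self) -> float:
        return float(self.eigenvalues.real.max())


def jacobian(s, p: ModelParameters) -> np.ndarray:
    """Analytic 6x6 Jacobian of the vector field at state ``s``.

    Constant external drives contribute nothing.  Under EI ablation the EI
    row/column reduce to an isolated zero-dynamics entry.
    """
    s = np.asarray(s, dtype=float)
    PY, I1, I2, EI, TC, RE = s
    fp = lambda x: sigmoid_derivative(x, p.epsilon)  # noqa: E731
    dPY, dI1, dI2, dTC, dRE = fp(PY), fp(I1), fp(I2), fp(TC), fp(RE)
    dEI = fp(EI) if p.ei_enabled else 0.0
    c_ei_py = p.c_ei_py if p.ei_enabled else 0.0
    c_ei_i1 = p.c_ei_i1 if p.ei_enabled else 0.0
    J = np.zeros((6, 6))
    J[0, 0] = p.tau_1 * (-1.0 + p.c_py_py * dPY)
    J[0, 1] = -p.tau_1 * p.c_i1_py * dI1
    J[0, 2] = -p.tau_1 * p.c_i2_py * dI2
    J[0, 3] = p.tau_1 * c_ei_py * dEI
    J[0, 4] = p.tau_1 * p.c_tc_py * dTC
    J[1, 0] = p.tau_2 * p.c_py_i1 * dPY
    J[1, 1] = -p.tau_2
    J[1, 2] = -p.tau_2 * p.c_i2_i1 * dI2
    J[1, 3] = p.tau_2 * c_ei_i1 * dEI
    J[1, 4] = p.tau_2 * p.c_tc_i1 * dTC
    J[2, 0] = p.tau_3 * p.c_py_i2 * dPY
    J[2, 1] = -p.tau_3 * p.c_i1_i2 * dI1
    J[2, 2] = -p.tau_3
    J[2, 4] = p.tau_3 * p.c_tc_i2 * dTC
    if p.ei_enabled:
        J[3, 0] = p.tau_4 * p.c_py_ei * dPY
        J[3, 1] = -p.tau_4 * p.c_i1_ei * dI1
        J[3, 3] = -p.tau_4
        J[3, 4] = p.tau_4 * p.c_tc_ei * dTC
    J[4, 0] = p.tau_5 * p.c_py_tc * dPY
    J[4, 4] = -p.tau_5
    J[4, 5] = -p.tau_5 * p.c_re_tc * dRE
    J[5, 0] = p.tau_6 * p.c_py_re * dPY
    J[5, 4] = p.tau_6 * p.c_tc_re * dTC
    J[5, 5] = p.tau_6 * (-1.0 - p.c_re_re * dRE)
    return J


def _classify_stability(eig: np.ndarray) -> str:
    re = eig.real
    has_complex = np.any(np.abs(eig.imag) > 1e-9)
    if np.all(re < 0):
        return "stable_focus" if has_complex else "stable_node"
    if np.all(re > 0):
        return "unstable"
    return "saddle" if np.any(re < 0) else "unstable"


def newton_equilibrium(
    p: ModelParameters,
    x0,
    n_py: float,
    n_tc: float,
    tol: float = 1e-13,
    max_iter: int = 200,
    max_halvings: int = 20,
):
    """Damped Newton iteration; returns the root or None.

    Step halving (up to ``max_halvings``) on residual increase.
    """
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        F = vector_field(x, p, n_py, n_tc)
        r = norm(F)
        if r < tol:
            return x
        try:
            dx = solve(jacobian(x, p), -F)
        except LinAlgError:
            return None
        lam = 1.0
        for _ in range(max_halvings + 1):
            xn = x + lam * dx
            if norm(vector_field(xn, p, n_py, n_tc)) < r:
                break
            lam *= 0.5
        else:
            return None
        x = xn
    return x if norm(vector_field(x, p, n_py, n_tc)) < RESIDUAL_TOL else None


def _record(p: ModelParameters, x: np.ndarray, n_py: float, n_tc: float) -> EquilibriumRecord:
    eig = eigvals(jacobian(x, p))
    return EquilibriumRecord(
        state=x,
        eigenvalues=eig,
        stability=_classify_stability(eig),
        residual=float(norm(vector_field(x, p, n_py, n_tc))),
    )


def find_equilibria(
    p: ModelParameters,
    d: DriveSpec | None = None,
    grid_points: int = 3,
    box=(-4.0, 2.0),
) -> list[EquilibriumRecord]:
    """All equilibria reachable by damped Newton from a deterministic
    multi-start grid over ``box``^6 (``grid_points`` per axis plus the
    origin), deduplicated at distance 1e-6.

    Requires constant inputs (a_py = a_tc = 0).
    """
    if d is None:
        d = DriveSpec()
    if not d.is_constant:
        raise ValueError("equilibrium analysis requires constant inputs")
    n_py = p.c_Npy_py * d.B_Npy
    n_tc = p.c_Ntc_tc * d.B_Ntc
    starts = [np.zeros(6)]
    axis = np.linspace(box[0], box[1], grid_points)
    starts += [np.array(c) for c in itertools.product(axis, repeat=6)]
    sols: list[np.ndarray] = []
    for x0 in starts:
        x = newton_equilibrium(p, x0, n_py, n_tc)
        if x is None:
            continue
        if not any(norm(x - s) < DEDUP_TOL for s in sols):
            sols.append(x)
    recs = [_record(p, x, n_py, n_tc) for x in sols]
    recs.sort(key=lambda r: norm(r.state))
    return recs


def leading_complex_real(eig: np.ndarray) -> float:
    """Real part of the leading complex-conjugate eigenvalue pair (largest
    real part among eigenvalues with nonzero imaginary part); falls back to
    the overall leading real part if the spectrum is entirely real."""
    cplx = eig[np.abs(eig.imag) > 1e-9]
    if cplx.size:
        return float(cplx.real.max())
    return float(eig.real.max())


class EquilibriumTracker:
    """Continuation of one equilibrium branch in a single parameter.

    Warm-started damped Newton from the last tracked state; when the
    branch is lost (e.g. beyond a fold) the branch is re-acquired with a
    multi-start search, selecting the equilibrium closest to the last
    tracked state.
    """

    def __init__(self, p: ModelParameters, param_name: str,
                 d: DriveSpec | None = None, x0=None):
        self.base = p
        self.param_name = param_name
        self.drive = d if d is not None else DriveSpec()
        if not self.drive.is_constant:
            raise ValueError("equilibrium tracking requires constant inputs")
        self._n_py = p.c_Npy_py * self.drive.B_Npy
        self._n_tc = p.c_Ntc_tc * self.drive.B_Ntc
        self.last_state = None if x0 is None else np.asarray(x0, dtype=float)

    def _params_at(self, value: float) -> ModelParameters:
        return self.base.replace(**{self.param_name: value})

    def _initial_state(self, p: ModelParameters) -> np.ndarray:
        x = newton_equilibrium(p, np.zeros(6), self._n_py, self._n_tc)
        if x is not None:
            return x
        recs = find_equilibria(p, self.drive)
        if not recs:
            raise BranchLostError(
                f"no equilibrium found at {self.param_name} = "
                f"{getattr(p, self.param_name)}"
            )
        return min(recs, key=lambda r: norm(r.state)).state

    def at(self, value: float) -> EquilibriumRecord:
        """Equilibrium record at ``param_name = value``, continuing the
        tracked branch."""
        p = self._params_at(value)
        if self.last_state is None:
            x = self._initial_state(p)
        else:
            x = newton_equilibrium(p, self.last_state, self._n_py, self._n_tc)
            if x is None:
                recs = find_equilibria(p, self.drive)
                if not recs:
                    raise BranchLostError(
                        f"equilibrium branch lost at "
                        f"{self.param_name} = {value}"
                    )
                x = min(recs, key=lambda r: norm(r.state - self.last_state)).state
        self.last_state = x
        return _record(p, x, self._n_py, self._n_tc)


def locate_hopf(
    p: ModelParameters,
    param_name: str,
    bracket,
    tol: float = 1e-4,
    d: DriveSpec | None = None,
    x0=None,
) -> float:
    """Bisect the parameter value where the tracked equilibrium's leading
    complex eigenvalue pair crosses zero real part.

    ``bracket`` is traversed from its first to its second element (either
    direction).  Raises NoCrossingError if the real part has the same sign
    at both ends, BranchLostError if the branch cannot be followed.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    tracker = EquilibriumTracker(p, param_name, d, x0=x0)
    g_lo = leading_complex_real(tracker.at(lo).eigenvalues)
    g_hi = leading_complex_real(tracker.at(hi).eigenvalues)
    if np.sign(g_lo) == np.sign(g_hi):
        raise NoCrossingError(
            f"leading eigenvalue real part has the same sign at both "
            f"bracket ends ({g_lo:.4g}, {g_hi:.4g})"
        )
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        g_mid = leading_complex_real(tracker.at(mid).eigenvalues)
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi, g_hi = mid, g_mid
    return 0.5 * (lo + hi)
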