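"""1D bifurcation sweeps, event detection, and 2D state maps.

A 1D sweep simulates the model at every value of a parameter grid,
recording the ranked extrema and dominant frequency of the trailing 2 s
window.  With attractor inheritance (default) the final state of each run
seeds the next grid point, so the sweep follows one attractor branch;
running the same grid in both directions and comparing the settled
attractors exposes bistable (hysteresis) windows whose edges approximate
fold-limit-cycle and subcritical-Hopf boundaries.  Period-doubling events
are read off the waveform: the count of distinct local-maximum levels
doubling between adjacent grid points.

A 2D map classifies the activity type (and dominant frequency) on a grid
over the two intracortical EI couplings at a fixed thalamus-to-EI
coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import StateLabel, classify_state
from .equilibria import (EquilibriumTracker, BranchLostError,
                         leading_complex_real)
from .features import FeatureSet, compute_features
from .model import DEFAULT_DT, DEFAULT_DURATION, SimulationDiverged, simulate
from .params import DriveSpec, ModelParameters

__all__ = [
    "BifurcationDiagram", "BifurcationEvent", "StateMap", "sweep_1d",
    "detect_period_doubling", "detect_bistable_windows", "map_2d",
]


@dataclass
class BifurcationEvent:
    type: str        # hopf | period_doubling | bistable_window_edge
    location: float
    direction: str   # forward | backward | both


@dataclass
class BifurcationDiagram:
    """Per-parameter-value waveform features along one sweep direction."""

    param_name: str
    param_values: np.ndarray
    features: list            # FeatureSet | None (None = diverged)
    maxima: list              # np.ndarray of local-max values per point
    minima: list
    direction: str
    eq_leading_real: np.ndarray | None = None   # tracked-branch eigenvalue
    events: list = field(default_factory=list)

    def labels(self) -> list:
        return [
            StateLabel.unclassified if f is None else classify_state(f)
            for f in self.features
        ]

    def ptp(self) -> np.ndarray:
        return np.array([np.nan if f is None else f.ptp for f in self.features])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, f, lab in zip(self.param_values, self.features, self.labels()):
            row = {"param": self.param_name, "value": v, "label": lab.value}
            row.update(f.to_row() if f is not None
                       else dict.fromkeys(FeatureSet(0, 0, 0, 0, 0, 0, 0).to_row(), np.nan))
            rows.append(row)
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"type": e.type, "location": e.location, "direction": e.direction}
             for e in self.events]
        )


def sweep_1d(
    p: ModelParameters,
    param_name: str,
    grid,
    d: DriveSpec | None = None,
    inherit: bool = True,
    s0=None,
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    attach_equilibria: bool = False,
) -> BifurcationDiagram:
    """Simulate along ``grid`` (traversed in the order given) and collect
    trailing-window features.

    With ``inherit`` the final state of one run seeds the next (attractor
    following); otherwise every run starts cold from ``s0`` (default the
    zero state).  Divergent grid points are recorded as missing and the
    sweep continues.  With ``attach_equilibria`` the tracked equilibrium
    branch's leading complex eigenvalue real part is recorded per point and
    its sign changes are attached as Hopf events.
    """
    if d is None:
        d = DriveSpec()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty parameter grid")
    steps = np.diff(grid)
    if grid.size > 1 and not (np.all(steps > 0) or np.all(steps < 0)):
        raise ValueError("parameter grid must be strictly monotone")
    direction = "backward" if (grid.size > 1 and steps[0] < 0) else "forward"
    base_s0 = np.zeros(6) if s0 is None else np.asarray(s0, dtype=float)
    state = base_s0
    feats: list = []
    maxima: list = []
    minima: list = []
    from .features import extract_extrema, analysis_window
    for v in grid:
        pv = p.replace(**{param_name: v})
        try:
            r = simulate(pv, d, duration=duration, dt=dt, s0=state)
        except SimulationDiverged:
            feats.append(None)
            maxima.append(np.array([]))
            minima.append(np.array([]))
            state = base_s0 if inherit else base_s0
            continue
        feats.append(compute_features(r))
        seg = analysis_window(r)
        mx, mn, _, _ = extract_extrema(seg)
        maxima.append(mx)
        minima.append(mn)
        if inherit:
            state = r.final_state
        else:
            state = base_s0
    diag = BifurcationDiagram(
        param_name=param_name, param_values=grid, features=feats,
        maxima=maxima, minima=minima, direction=direction,
    )
    if attach_equilibria:
        _attach_equilibrium_branch(diag, p, d)
    diag.events.extend(
        BifurcationEvent("period_doubling", loc, direction)
        for loc in detect_period_doubling(diag)
    )
    return diag


def _attach_equilibrium_branch(diag: BifurcationDiagram,
                               p: ModelParameters, d: DriveSpec) -> None:
    tracker = EquilibriumTracker(p, diag.param_name, d)
    vals = np.full(diag.param_values.size, np.nan)
    for i, v in enumerate(diag.param_values):
        try:
            vals[i] = leading_complex_real(tracker.at(v).eigenvalues)
        except BranchLostError:
            break
    diag.eq_leading_real = vals
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        loc = 0.5 * (diag.param_values[i] + diag.param_values[i + 1])
        diag.events.append(BifurcationEvent("hopf", loc, diag.direction))


def detect_period_doubling(diag: BifurcationDiagram) -> list:
    """Grid midpoints where the distinct local-maximum level count doubles
    (1 -> 2 or 2 -> 4) between adjacent points."""
    locs = []
    counts = [None if f is None else f.n_max_clusters for f in diag.features]
    for i in range(len(counts) - 1):
        a, b = counts[i], counts[i + 1]
        if a is None or b is None:
            continue
        if (a, b) in ((1, 2), (2, 4)):
            locs.append(0.5 * (diag.param_values[i] + diag.param_values[i + 1]))
    return locs


def _attractors_differ(diag_a: BifurcationDiagram, diag_b: BifurcationDiagram,
                       i: int, j: int, tol: float) -> bool:
    fa, fb = diag_a.features[i], diag_b.features[j]
    if fa is None or fb is None:
        return fa is not fb
    # compare amplitude envelope of the settled attractors
    for attr in ("ptp", "Pmax1", "Pmin1"):
        a, b = getattr(fa, attr), getattr(fb, attr)
        if np.isnan(a) and np.isnan(b):
            continue
        if np.isnan(a) != np.isnan(b) or abs(a - b) > tol:
            return True
    return False


def detect_bistable_windows(
    forward: BifurcationDiagram,
    backward: BifurcationDiagram,
    tol: float = 0.01,
) -> list:
    """Parameter windows where forward and backward sweeps settle onto
    different attractors (hysteresis).

    Both diagrams must cover the same grid in opposite directions.
    Returns a list of (lower_edge, upper_edge) tuples; edges approximate
    fold-limit-cycle / subcritical-Hopf boundaries.
    """
    fv = forward.param_values
    bv = backward.param_values
    if fv.size != bv.size or not np.allclose(fv, bv[::-1]):
        raise ValueError("sweeps must share one grid in opposite directions")
    n = fv.size
    differ = np.array([
        _attractors_differ(forward, backward, i, n - 1 - i, tol)
        for i in range(n)
    ])
    windows = []
    i = 0
    while i < n:
        if differ[i]:
            j = i
            while j + 1 < n and differ[j + 1]:
                j += 1
            windows.append((float(fv[i]), float(fv[j])))
            i = j + 1
        else:
            i += 1
    for lo, hi in windows:
        forward.events.append(
            BifurcationEvent("bistable_window_edge", lo, "both"))
        forward.events.append(
            BifurcationEvent("bistable_window_edge", hi, "both"))
    return windows


@dataclass
class StateMap:
    """Activity labels and dominant frequencies over a 2D coupling grid."""

    grid_py_ei: np.ndarray
    grid_i1_ei: np.ndarray
    c_tc_ei: float
    labels: np.ndarray        # (n_py_ei, n_i1_ei) of StateLabel
    DF: np.ndarray            # same shape, Hz

    def label_counts(self) -> dict:
        flat = list(self.labels.ravel())
        return {lab: sum(1 for x in flat if x is lab) for lab in StateLabel}

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.grid_py_ei, name="c_py_ei")
        cols = pd.Index(self.grid_i1_ei, name="c_i1_ei")
        lab = pd.DataFrame([[l.value for l in row] for row in self.labels],
                           index=idx, columns=cols)
        df = pd.DataFrame(self.DF, index=idx, columns=cols)
        return lab, df


def map_2d(
    p: ModelParameters,
    grid_py_ei,
    grid_i1_ei,
    c_tc_ei: float,
    d: DriveSpec | None = None,
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    s0=None,
) -> StateMap:
    """Simulate + classify on the (c_py_ei, c_i1_ei) grid at fixed c_tc_ei.

    Every cell starts from the same initial state (cold start), so the map
    reflects the attractor reached from a common condition.  Divergent
    cells are labelled unclassified with NaN dominant frequency.
    """
    if d is None:
        d = DriveSpec()
    gx = np.asarray(grid_py_ei, dtype=float)
    gy = np.asarray(grid_i1_ei, dtype=float)
    s0 = np.zeros(6) if s0 is None else np.asarray(s0, dtype=float)
    labels = np.empty((gx.size, gy.size), dtype=object)
    dfs = np.full((gx.size, gy.size), np.nan)
    for i, a in enumerate(gx):
        for j, b in enumerate(gy):
            pv = p.replace(c_py_ei=a, c_i1_ei=b, c_tc_ei=c_tc_ei)
            try:
                r = simulate(pv, d, duration=duration, dt=dt, s0=s0)
            except SimulationDiverged:
                labels[i, j] = StateLabel.unclassified
                continue
            f = compute_features(r)
            labels[i, j] = classify_state(f)
            dfs[i, j] = f.DF
    return StateMap(grid_py_ei=gx, grid_i1_ei=gy, c_tc_ei=c_tc_ei,
                    labels=labels, DF=dfs)
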