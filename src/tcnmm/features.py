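"""Waveform features of the steady-state window: dominant frequency and
ranked extrema.

All bifurcation and classification analysis works on the last 2 s of a
60 s run (512 samples at the default step of 0.0039 s).  From that window
we take the dominant frequency of the mean-removed periodogram and the
local extrema of the output, ranked from large to small: the largest and
smallest local maxima (Pmax1, Pmax2) and the largest and smallest local
minima (Pmin1, Pmin2).  Windows whose peak-to-peak amplitude falls below a
small threshold are treated as fixed-point (non-oscillatory) regimes:
their dominant frequency is reported as 0 and the extrema as absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SimulationResult

__all__ = [
    "FeatureSet", "analysis_window", "extract_extrema",
    "dominant_frequency", "compute_features",
    "AMPLITUDE_THRESHOLD", "LEVEL_TOL", "DEFAULT_WINDOW",
]

AMPLITUDE_THRESHOLD = 1e-3   # model units; below this the window is "flat"
LEVEL_TOL = 1e-3             # tolerance when clustering extremum levels
DEFAULT_WINDOW = 2.0         # seconds


@dataclass
class FeatureSet:
    """Dominant frequency and ranked extrema of one analysis window.

    Extrema fields are NaN when the window is flat (no oscillation) or has
    no interior extrema.  ``mean`` is the window mean level, used to
    separate the negative-offset slow-rhythmic fixed point from the normal
    resting state.
    """

    DF: float
    Pmax1: float
    Pmax2: float
    Pmin1: float
    Pmin2: float
    ptp: float
    n_max_clusters: int
    mean: float = float("nan")

    @property
    def oscillatory(self) -> bool:
        return self.ptp >= AMPLITUDE_THRESHOLD

    def to_row(self) -> dict:
        return {
            "DF": self.DF, "Pmax1": self.Pmax1, "Pmax2": self.Pmax2,
            "Pmin1": self.Pmin1, "Pmin2": self.Pmin2, "ptp": self.ptp,
            "n_max_clusters": self.n_max_clusters, "mean": self.mean,
        }

    @classmethod
    def from_row(cls, row: dict) -> "FeatureSet":
        return cls(
            DF=float(row["DF"]), Pmax1=float(row["Pmax1"]),
            Pmax2=float(row["Pmax2"]), Pmin1=float(row["Pmin1"]),
            Pmin2=float(row["Pmin2"]), ptp=float(row["ptp"]),
            n_max_clusters=int(row["n_max_clusters"]),
            mean=float(row.get("mean", "nan")),
        )


def analysis_window(r: SimulationResult, window: float = DEFAULT_WINDOW) -> np.ndarray:
    """Trailing ``window`` seconds of the output series.

    With the defaults (60 s at dt = 0.0039 s, window 2 s) this is the last
    512 samples, covering t in (58, 60].
    """
    n = int(window / r.dt)
    if n > len(r.output):
        raise ValueError(
            f"window of {window} s ({n} samples) longer than the "
            f"simulation ({len(r.output)} samples)"
        )
    return r.output[-n:]


def extract_extrema(segment, level_tol: float = LEVEL_TOL):
    """Interior local maxima and minima of a series, with level clustering.

    An extremum is a strict sign change of the first difference (plateau
    samples are carried through).  Extremum values are grouped into
    distinct levels with tolerance ``level_tol`` so that period-doubled
    waveforms can be recognized by their level count.

    Returns ``(maxima, minima, max_levels, min_levels)``: the raw extremum
    values in series order and the sorted cluster representatives
    (cluster means, descending).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("segment must have at least 3 samples")
    d = np.diff(x)
    # drop zero differences so plateaus don't mask the sign change
    nz = d != 0.0
    idx = np.nonzero(nz)[0]
    maxima, minima = [], []
    if idx.size >= 2:
        dd = d[idx]
        sign_change = np.nonzero(dd[:-1] * dd[1:] < 0)[0]
        for k in sign_change:
            i = idx[k + 1]  # first sample after the turn
            if dd[k] > 0:
                maxima.append(x[i])
            else:
                minima.append(x[i])
    return (
        np.array(maxima), np.array(minima),
        _cluster_levels(maxima, level_tol),
        _cluster_levels(minima, level_tol),
    )


def _cluster_levels(values, tol: float) -> np.ndarray:
    """Greedy 1D clustering: sorted values split where the gap exceeds tol;
    returns cluster means, descending."""
    if len(values) == 0:
        return np.array([])
    v = np.sort(np.asarray(values, dtype=float))
    splits = np.nonzero(np.diff(v) > tol)[0]
    groups = np.split(v, splits + 1)
    return np.array(sorted((g.mean() for g in groups), reverse=True))


def dominant_frequency(
    segment,
    dt: float,
    amp_threshold: float = AMPLITUDE_THRESHOLD,
) -> float:
    """Frequency of the maximum-power periodogram peak (f > 0); 0 Hz for
    sub-threshold (flat) windows.

    The peak-bin frequency is refined by parabolic interpolation of
    log-power over the three bins around the maximum, giving sub-bin
    resolution (a 2 s window alone only resolves 0.5 Hz).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 16:
        raise ValueError("segment too short for a spectral estimate")
    if np.ptp(x) < amp_threshold:
        return 0.0
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, dt)
    k = 1 + int(np.argmax(power[1:]))
    if 1 < k < power.size - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        la, lb, lc = np.log(power[k - 1: k + 2])
        denom = la - 2.0 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((k + delta) * (freqs[1] - freqs[0]))


def compute_features(
    r: SimulationResult,
    window: float = DEFAULT_WINDOW,
    amp_threshold: float = AMPLITUDE_THRESHOLD,
    level_tol: float = LEVEL_TOL,
) -> FeatureSet:
    """FeatureSet of the trailing analysis window of a simulation."""
    seg = analysis_window(r, window)
    return features_of_segment(seg, r.dt, amp_threshold, level_tol)


def features_of_segment(
    seg,
    dt: float,
    amp_threshold: float = AMPLITUDE_THRESHOLD,
    level_tol: float = LEVEL_TOL,
) -> FeatureSet:
    """FeatureSet of an arbitrary uniformly sampled segment."""
    seg = np.asarray(seg, dtype=float)
    ptp = float(np.ptp(seg))
    mean = float(seg.mean())
    nan = float("nan")
    if ptp < amp_threshold:
        return FeatureSet(DF=0.0, Pmax1=nan, Pmax2=nan, Pmin1=nan,
                          Pmin2=nan, ptp=ptp, n_max_clusters=0, mean=mean)
    df = dominant_frequency(seg, dt, amp_threshold)
    maxima, minima, max_levels, min_levels = extract_extrema(seg, level_tol)
    return FeatureSet(
        DF=df,
        Pmax1=float(maxima.max()) if maxima.size else nan,
        Pmax2=float(maxima.min()) if maxima.size else nan,
        Pmin1=float(minima.max()) if minima.size else nan,
        Pmin2=float(minima.min()) if minima.size else nan,
        ptp=ptp,
        n_max_clusters=int(max_levels.size),
        mean=mean,
    )
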