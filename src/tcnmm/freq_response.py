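"""Frequency response to sinusoidal cortical or sensory drive.

The model is driven with a biased sinusoid on one channel (cortical input
to PY or sensory input to TC), the other channel held at its constant
bias, over a grid of drive frequencies.  Per frequency we record the
steady-state peak-to-peak amplitude and dominant frequency of the trailing
2 s window.  In the resting (interictal) configuration the model behaves
as a linear resonator — a smooth band-pass (sensory) or low-pass
(cortical) amplitude curve with a single resonance.  Shifted into the
preictal configuration it becomes a non-linear resonator: the amplitude
curve develops abrupt jumps (the jump phenomenon of driven non-linear
oscillators) and aperiodic bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .features import compute_features, analysis_window
from .model import DEFAULT_DT, DEFAULT_DURATION, SimulationDiverged, simulate
from .params import DriveSpec, ModelParameters

__all__ = [
    "FrequencyResponse", "frequency_sweep", "detect_resonance",
    "detect_jumps", "refine_resonance", "state_switch_protocol",
    "StateSwitchResult",
]

CHANNELS = ("cortical", "sensory")


@dataclass
class FrequencyResponse:
    """Steady-state response curve versus drive frequency."""

    channel: str
    freqs: np.ndarray
    ptp: np.ndarray             # steady-state peak-to-peak output amplitude
    DF: np.ndarray              # dominant output frequency per drive freq
    features: list              # FeatureSet | None per frequency
    aperiodic: np.ndarray       # True where the driven output is not
                                # phase-locked to the drive (chaos proxy)
    params: ModelParameters
    amp: float

    def to_frame(self) -> pd.DataFrame:
        n_clusters = [np.nan if f is None else f.n_max_clusters
                      for f in self.features]
        return pd.DataFrame({
            "freq": self.freqs, "ptp": self.ptp, "DF": self.DF,
            "n_max_clusters": n_clusters, "aperiodic": self.aperiodic,
        })


def _drive_for(channel: str, freq: float, amp: float,
               base: DriveSpec) -> DriveSpec:
    if channel == "cortical":
        return base.replace(a_py=amp, fpy=freq, a_tc=0.0)
    if channel == "sensory":
        return base.replace(a_tc=amp, ftc=freq, a_py=0.0)
    raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")


def _lock_score(seg: np.ndarray, dt: float, freq: float) -> float:
    """Normalized autocorrelation of the window at one drive period;
    near 1 for output phase-locked to the drive."""
    lag = int(round(1.0 / (freq * dt))) if freq > 0 else 0
    if lag <= 0 or lag >= seg.size - 2:
        return 1.0
    x = seg - seg.mean()
    denom = float(np.dot(x, x))
    if denom < 1e-300:
        return 1.0
    a, b = x[:-lag], x[lag:]
    sa, sb = np.dot(a, a), np.dot(b, b)
    if sa <= 0 or sb <= 0:
        return 1.0
    return float(np.dot(a, b) / np.sqrt(sa * sb))


def frequency_sweep(
    p: ModelParameters,
    channel: str,
    freqs,
    amp: float = 0.02,
    base_drive: DriveSpec | None = None,
    inherit: bool = True,
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    s0=None,
    lock_threshold: float = 0.9,
) -> FrequencyResponse:
    """Sweep the drive frequency on one channel; the other channel's
    amplitude is held at zero.

    With ``inherit`` the final state at one frequency seeds the next, so
    the sweep follows one response branch (needed to expose hysteresis and
    jumps).
    """
    if base_drive is None:
        base_drive = DriveSpec()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size and np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    s = np.zeros(6) if s0 is None else np.asarray(s0, dtype=float)
    ptp = np.full(freqs.size, np.nan)
    dfreq = np.full(freqs.size, np.nan)
    aper = np.zeros(freqs.size, dtype=bool)
    feats: list = []
    for i, f0 in enumerate(freqs):
        dv = _drive_for(channel, f0, amp, base_drive)
        try:
            r = simulate(p, dv, duration=duration, dt=dt, s0=s)
        except SimulationDiverged:
            feats.append(None)
            continue
        fs = compute_features(r)
        feats.append(fs)
        ptp[i] = fs.ptp
        dfreq[i] = fs.DF
        if fs.oscillatory:
            aper[i] = _lock_score(analysis_window(r), dt, f0) < lock_threshold
        if inherit:
            s = r.final_state
    return FrequencyResponse(channel=channel, freqs=freqs, ptp=ptp, DF=dfreq,
                             features=feats, aperiodic=aper, params=p, amp=amp)


def detect_resonance(
    fr: FrequencyResponse,
    smooth: int = 5,
    prominence_frac: float = 0.05,
) -> np.ndarray:
    """Resonance peak frequencies of the amplitude curve, sorted by
    descending peak amplitude.

    The curve is smoothed with a short moving average; interior local
    maxima above a prominence threshold (a fraction of the curve's range)
    are returned.  If the curve is monotone the boundary maximum is
    returned alone.
    """
    a = fr.ptp.copy()
    ok = np.isfinite(a)
    if not ok.any():
        return np.array([])
    a[~ok] = np.interp(fr.freqs[~ok], fr.freqs[ok], a[ok])
    smooth = min(smooth, a.size)  # kernel must not exceed the curve
    if smooth > 1:
        kernel = np.ones(smooth)
        # edge-normalized moving average (plain "same" convolution would
        # taper the boundary values toward zero)
        a = (np.convolve(a, kernel, mode="same")
             / np.convolve(np.ones_like(a), kernel, mode="same"))
    rng = float(a.max() - a.min())
    if rng <= 0:
        return np.array([])
    idx, props = find_peaks(a, prominence=prominence_frac * rng)
    if idx.size == 0:
        return np.array([fr.freqs[int(np.argmax(a))]])
    order = np.argsort(-a[idx])
    return fr.freqs[idx[order]]


def refine_resonance(
    p: ModelParameters,
    fr: FrequencyResponse,
    step: float = 0.01,
    span: float = 0.15,
    lead_in: int = 4,
    **sweep_kwargs,
) -> float:
    """Re-sweep around the strongest resonance at a finer step and return
    the refined peak frequency.

    The fine sweep starts ``lead_in`` extra grid points below the scored
    window so attractor inheritance settles before measurement; the peak
    is taken over the window [peak - span, peak + span] only.
    """
    peaks = detect_resonance(fr)
    if peaks.size == 0:
        raise ValueError("no resonance peak to refine")
    f0 = float(peaks[0])
    lo = max(step, f0 - span)
    start = max(step, lo - lead_in * step)
    fine = np.arange(start, f0 + span + step / 2, step)
    fr2 = frequency_sweep(p, fr.channel, fine, amp=fr.amp, **sweep_kwargs)
    ok = np.isfinite(fr2.ptp) & (fr2.freqs >= lo - step / 2)
    return float(fr2.freqs[ok][np.argmax(fr2.ptp[ok])])


def detect_jumps(
    fr: FrequencyResponse,
    jump_factor: float = 5.0,
    jump_tol: float | None = None,
    window: int = 5,
) -> np.ndarray:
    """Frequencies of abrupt amplitude discontinuities.

    A jump is an adjacent-point amplitude difference exceeding
    ``jump_factor`` times the median adjacent difference of its local
    neighbourhood (``window`` points on each side, the point itself
    excluded).  A genuine discontinuity is a local outlier; the steep but
    smooth flank of a resonance peak has neighbouring differences of the
    same size and is not flagged.  An explicit absolute ``jump_tol``
    replaces the relative rule.  Returns interval midpoints, ascending.
    """
    ok = np.isfinite(fr.ptp)
    f = fr.freqs[ok]
    a = fr.ptp[ok]
    if a.size < 3:
        return np.array([])
    d = np.abs(np.diff(a))
    if jump_tol is not None:
        idx = np.nonzero(d > jump_tol)[0]
        return 0.5 * (f[idx] + f[idx + 1])
    idx = []
    for i in range(d.size):
        lo = max(0, i - window)
        hi = min(d.size, i + window + 1)
        neighbours = np.delete(d[lo:hi], i - lo)
        med = float(np.median(neighbours))
        if med <= 0:
            med = float(np.mean(neighbours)) or 1e-12
        if d[i] > jump_factor * med:
            idx.append(i)
    idx = np.asarray(idx, dtype=int)
    return 0.5 * (f[idx] + f[idx + 1])


@dataclass
class StateSwitchResult:
    """Concatenated output of a piecewise-constant c_py_ei schedule."""

    times: np.ndarray
    output: np.ndarray
    epochs: list                    # (t_start, t_end, c_py_ei)
    epoch_features: list            # FeatureSet per epoch
    dt: float


def state_switch_protocol(
    p: ModelParameters,
    schedule=((20.0, 0.76), (20.0, 0.748), (20.0, 0.76)),
    d: DriveSpec | None = None,
    dt: float = DEFAULT_DT,
    s0=None,
    feature_window: float = 2.0,
) -> StateSwitchResult:
    """Simulate with c_py_ei following a piecewise-constant schedule.

    ``schedule`` is a sequence of (duration_seconds, c_py_ei) epochs; the
    state is carried continuously across epoch boundaries.  The default
    drive is a 1 Hz cortical sinusoid of amplitude 0.02 with the sensory
    channel constant.  Per-epoch features are computed on the trailing
    ``feature_window`` seconds of each epoch.
    """
    if d is None:
        d = DriveSpec(a_py=0.02, fpy=1.0, a_tc=0.0)
    s = np.zeros(6) if s0 is None else np.asarray(s0, dtype=float)
    t = 0.0
    times_parts, out_parts, epochs, efeats = [], [], [], []
    from .features import features_of_segment
    for k, (dur, value) in enumerate(schedule):
        pv = p.replace(c_py_ei=value)
        r = simulate(pv, d, duration=dur, dt=dt, s0=s, t0=t)
        keep = slice(None) if k == 0 else slice(1, None)
        times_parts.append(r.times[keep])
        out_parts.append(r.output[keep])
        epochs.append((t, float(r.times[-1]), value))
        n = int(feature_window / dt)
        efeats.append(features_of_segment(r.output[-n:], dt))
        s = r.final_state
        t = float(r.times[-1])
    return StateSwitchResult(
        times=np.concatenate(times_parts),
        output=np.concatenate(out_parts),
        epochs=epochs, epoch_features=efeats, dt=dt,
    )
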