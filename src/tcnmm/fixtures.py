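"""Deterministic synthetic series and canned feature sets for testing the
feature extractor and classifier without running the model.

Everything flows from one explicit seed; model dynamics themselves are
deterministic and need no seeding.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureSet

__all__ = ["generate_fixtures"]

_DT = 1.0 / 256.0


def _sine(freq, duration=2.0, amp=1.0, offset=0.0, dt=_DT):
    t = np.arange(0.0, duration, dt)
    return offset + amp * np.sin(2 * np.pi * freq * t)


def _two_amplitude_spikes(peaks=(1.0, 0.6), n_pairs=6, width=16):
    """Alternating-amplitude spike train: the waveform signature of a
    period-doubled cycle (two distinct maximum levels)."""
    parts = []
    half = np.hanning(width)
    for _ in range(n_pairs):
        for pk in peaks:
            parts.append(pk * half)
    return np.concatenate(parts)


def _damped_oscillation(offset=-0.4, amp=0.5, freq=6.0, decay=6.0,
                        duration=2.0, dt=_DT):
    t = np.arange(0.0, duration, dt)
    return offset + amp * np.exp(-decay * t) * np.sin(2 * np.pi * freq * t)


def _swd_like(freq=3.0, duration=2.0, dt=_DT, spike_gain=0.35,
              min_gap=0.05):
    """Spike-and-wave-like series with two coexisting minima levels
    separated by ``min_gap``."""
    t = np.arange(0.0, duration, dt)
    base = np.sin(2 * np.pi * freq * t)
    spike = spike_gain * np.sin(2 * np.pi * 2 * freq * t)
    x = base + spike
    period = int(round(1.0 / (freq * dt)))
    # deepen every second trough to split the minima into two levels
    for k, i0 in enumerate(range(0, x.size - period, period)):
        if k % 2 == 1:
            seg = slice(i0, i0 + period)
            x[seg] = x[seg] - min_gap * (x[seg] < np.percentile(x[seg], 20))
    return x

# Canned FeatureSets matching each activity type's defining ranges.
_CANNED = {
    "normal": FeatureSet(DF=0.0, Pmax1=float("nan"), Pmax2=float("nan"),
                         Pmin1=float("nan"), Pmin2=float("nan"),
                         ptp=1e-5, n_max_clusters=0, mean=0.2),
    "preictal": FeatureSet(DF=2.5, Pmax1=0.05, Pmax2=0.0, Pmin1=-0.03,
                           Pmin2=-0.04, ptp=0.09, n_max_clusters=2,
                           mean=-0.08),
    "slow_rhythmic": FeatureSet(DF=0.0, Pmax1=float("nan"),
                                Pmax2=float("nan"), Pmin1=float("nan"),
                                Pmin2=float("nan"), ptp=1e-5,
                                n_max_clusters=0, mean=-0.4),
    "typical_absence": FeatureSet(DF=3.0, Pmax1=0.4, Pmax2=0.4, Pmin1=-0.2,
                                  Pmin2=-0.5, ptp=0.9, n_max_clusters=1,
                                  mean=-0.05),
    "atypical_absence": FeatureSet(DF=5.0, Pmax1=0.3, Pmax2=0.3,
                                   Pmin1=-0.2, Pmin2=-0.25, ptp=0.55,
                                   n_max_clusters=1, mean=0.0),
    "clonic": FeatureSet(DF=3.0, Pmax1=0.5, Pmax2=0.498, Pmin1=-0.4,
                         Pmin2=-0.402, ptp=0.9, n_max_clusters=1,
                         mean=0.0),
    "tonic": FeatureSet(DF=16.0, Pmax1=0.1, Pmax2=0.099, Pmin1=-0.05,
                        Pmin2=-0.052, ptp=0.15, n_max_clusters=1,
                        mean=0.1),
}


def generate_fixtures(seed: int = 0) -> dict:
    """Deterministic fixture bundle keyed by name.

    ``series`` holds (values, dt) pairs; ``feature_sets`` canned
    FeatureSets for each activity type.  Identical seeds give identical
    bundles.
    """
    rng = np.random.default_rng(seed)
    series = {
        "sine_3hz": (_sine(3.0), _DT),
        "sine_3hz_2s_256hz_one_period": (_sine(3.0, duration=1.0 / 3.0), _DT),
        "two_amplitude_spikes": (_two_amplitude_spikes(), _DT),
        "damped_negative_offset": (_damped_oscillation(), _DT),
        "constant": (np.full(512, 0.2), _DT),
        "swd_like": (_swd_like(), _DT),
        "noise": (0.01 * rng.standard_normal(512), _DT),
        "mixed_2_5hz": ((0.3 * _sine(2.0) + _sine(5.0)), _DT),
    }
    return {"seed": seed, "series": series,
            "feature_sets": dict(_CANNED)}
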