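"""Seven-way activity classification from waveform features.

The model's cortical-mean output falls into seven activity types
distinguished by dominant frequency (DF), amplitude, and the spread of
ranked extrema:

================  =====================  =================================
label             dominant frequency     signature
================  =====================  =================================
normal            0 (fixed point)        resting level above -0.1
slow_rhythmic     0 (stable focus)       resting level in (-0.8, -0.1)
preictal          DF < 3.5 Hz            low-amplitude spikes (ptp < 0.15)
clonic            2-4 Hz                 high-amplitude slow waves,
                                         single minima level
typical_absence   2-4 Hz                 spike-and-wave: minima spread
                                         > 0.004
atypical_absence  DF > 4 or < 2 Hz       minima spread > 0.01
tonic             DF >= 14 Hz            fast spiking, minima spread < 0.01
================  =====================  =================================

The rule boundaries overlap (preictal/clonic share the slow band;
clonic/typical absence share DF in [2, 4]); a fixed precedence order
resolves them, testing the narrower bounded conditions first.  The
preictal/clonic separator is amplitude (the preictal state is the
low-amplitude precursor of the high-amplitude clonic discharge), and the
clonic/absence separator is the minima spread: a spike-and-wave cycle has
two distinct trough levels, a clonic slow wave only one.
"""

from __future__ import annotations

import enum
import math

from .features import AMPLITUDE_THRESHOLD, FeatureSet

__all__ = ["StateLabel", "classify_state", "LABEL_TYPES"]


class StateLabel(str, enum.Enum):
    """Activity types, ordered as Type1..Type7 plus a catch-all."""

    normal = "normal"
    preictal = "preictal"
    slow_rhythmic = "slow_rhythmic"
    typical_absence = "typical_absence"
    atypical_absence = "atypical_absence"
    clonic = "clonic"
    tonic = "tonic"
    unclassified = "unclassified"

    @property
    def type_number(self) -> int | None:
        """1..7 for the named activity types, None for unclassified."""
        order = [
            StateLabel.normal, StateLabel.preictal, StateLabel.slow_rhythmic,
            StateLabel.typical_absence, StateLabel.atypical_absence,
            StateLabel.clonic, StateLabel.tonic,
        ]
        try:
            return order.index(self) + 1
        except ValueError:
            return None


LABEL_TYPES = {lab: lab.type_number for lab in StateLabel}


def _spread(a: float, b: float) -> float:
    """a - b, NaN-safe: a single extremum level means zero spread."""
    if math.isnan(a) or math.isnan(b):
        return 0.0
    return a - b


def classify_state(f: FeatureSet) -> StateLabel:
    """Map a FeatureSet to exactly one StateLabel (total function).

    Precedence: tonic, then fixed-point regimes (normal / slow rhythmic by
    resting level), then preictal, clonic, typical absence, atypical
    absence; anything left is unclassified.
    """
    dmax = _spread(f.Pmax1, f.Pmax2)
    dmin = _spread(f.Pmin1, f.Pmin2)
    # (1) tonic: fast spiking with a single trough level
    if f.DF >= 14 and dmin < 0.01:
        return StateLabel.tonic
    # (2) fixed point (flat window): resting level separates slow rhythmic
    #     (stable focus at negative output) from normal background
    if f.ptp < AMPLITUDE_THRESHOLD:
        if -0.8 < f.mean < -0.1:
            return StateLabel.slow_rhythmic
        return StateLabel.normal
    # (3) preictal: slow low-amplitude spikes (the precursor band between
    #     oscillation onset and the high-amplitude clonic discharge)
    if f.DF < 3.5 and dmin < 0.2 and dmax < 0.12 and f.ptp < 0.15:
        return StateLabel.preictal
    # (4) clonic: slow high-amplitude waves, single minima level
    if 2 <= f.DF <= 4 and dmin < 0.004:
        return StateLabel.clonic
    # (5) typical absence: spike-and-wave with distinct minima levels
    if 2 < f.DF < 4 and dmin > 0.004:
        return StateLabel.typical_absence
    # (6) atypical absence
    if (f.DF > 4 or f.DF < 2) and dmin > 0.01:
        return StateLabel.atypical_absence
    return StateLabel.unclassified
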