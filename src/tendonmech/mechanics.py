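"""Force-signal conditioning and conversion to tendon force.

The dynamometer measures the force applied by the leg at a cuff above the
malleolus.  Multiplying by the external moment arm (cuff to knee rotational
axis) gives the knee extension moment; dividing that moment by the internal
moment arm (patellar tendon to lateral epicondyle) gives the force carried by
the tendon.  The raw signal is low-pass filtered (zero-phase Butterworth,
30 Hz default cut-off) before either conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class ForceTrace:
    """A sampled force signal.

    Parameters
    ----------
    samples : ndarray
        Force in newtons, one value per sample.
    rate : float
        Sampling rate in Hz (1,000 Hz in the acquisition protocol).
    trigger_index : int
        Sample index at which ultrasound frame 0 was captured.
    """

    samples: np.ndarray
    rate: float
    trigger_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not (0 <= self.trigger_index < len(self.samples)):
            raise ValueError(
                f"trigger_index {self.trigger_index} outside trace of "
                f"length {len(self.samples)}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass(frozen=True)
class MomentArms:
    """Lever arms converting cuff force -> knee moment -> tendon force.

    ``external_arm``: cuff mid-width to the knee rotational axis, metres.
    ``internal_arm``: patellar tendon frontal edge to the lateral epicondyle,
    metres (mean of two photograph analyses; the same value is reused for the
    pre and post sessions of a participant).
    """

    external_arm: float
    internal_arm: float

    def __post_init__(self) -> None:
        if self.external_arm <= 0 or self.internal_arm <= 0:
            raise ValueError("moment arms must be positive")
        if self.internal_arm >= self.external_arm:
            raise ValueError(
                "internal arm (tendon lever) must be shorter than the external "
                f"arm; got internal={self.internal_arm}, external={self.external_arm}"
            )


def lowpass_filter(trace: ForceTrace, cutoff: float = 30.0, order: int = 4) -> ForceTrace:
    """Zero-phase Butterworth low-pass filter of a force trace.

    Applied forward-backward (``filtfilt``) so that no phase lag is introduced
    between the force signal and the synchronously triggered ultrasound
    frames.  Length and trigger index are preserved.
    """
    nyquist = trace.rate / 2.0
    if not (0 < cutoff < nyquist):
        raise ValueError(f"cutoff must be in (0, {nyquist}) Hz, got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.rate, output="sos")
    # reflective padding avoids ramp-end transients
    filtered = signal.sosfiltfilt(sos, trace.samples, padtype="even")
    return replace(trace, samples=filtered)


def knee_moment(trace: ForceTrace, arms: MomentArms) -> np.ndarray:
    """Knee extension moment in N*m: cuff force times the external arm."""
    return trace.samples * arms.external_arm


def tendon_force(moment: np.ndarray, arms: MomentArms) -> np.ndarray:
    """Patellar tendon force in N: knee moment divided by the internal arm."""
    if arms.internal_arm <= 0:
        raise ValueError("internal moment arm must be positive")
    return np.asarray(moment, dtype=float) / arms.internal_arm


def tendon_force_trace(trace: ForceTrace, arms: MomentArms, cutoff: float = 30.0) -> ForceTrace:
    """Convenience composition: filter, then convert cuff force to tendon force."""
    filtered = lowpass_filter(trace, cutoff=cutoff)
    tf = tendon_force(knee_moment(filtered, arms), arms)
    return replace(filtered, samples=tf)
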