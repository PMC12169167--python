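"""Shear-wave-velocity QC and summarisation.

Tendon tissue is stiff enough that shear-wave velocities can hit the
instrument ceiling (20 m/s).  To avoid saturation bias, a recording is
discarded when more than 5% of its pixels — as a fraction averaged across
frames — exceed 90% of the maximal measurable velocity.  Passing recordings
are summarised by their mean pixel velocity, per side (medial/lateral) and as
the unweighted mean of both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class SWVRecording:
    """Per-frame 2D velocity pixel maps (m/s) from one probe placement.

    ``roi`` is an optional boolean mask restricting both the saturation count
    and the mean to the tendon region; without it the whole map is used.
    """

    maps: np.ndarray  # (n_frames, rows, cols), m/s
    side: str = "lateral"
    v_max: float = 20.0
    saturation_threshold_fraction: float = 0.05
    saturation_velocity_fraction: float = 0.90
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim == 2:
            maps = maps[None]
        if maps.ndim != 3 or maps.shape[0] < 1 or maps[0].size == 0:
            raise ValueError("maps must be a non-empty (n_frames, rows, cols) stack")
        if np.any(maps < 0) or np.any(maps > self.v_max):
            raise ValueError(f"pixel velocities must lie in [0, {self.v_max}] m/s")
        object.__setattr__(self, "maps", maps)
        if self.roi is not None:
            roi = np.asarray(self.roi, dtype=bool)
            if roi.shape != maps.shape[1:] or not roi.any():
                raise ValueError("roi must match the map shape and select >= 1 pixel")
            object.__setattr__(self, "roi", roi)


@dataclass(frozen=True)
class SWVSummary:
    """QC verdict and mean velocity of one recording."""

    side: str
    n_frames: int
    saturation_fraction: float
    passed_qc: bool
    mean_velocity: float | None  # None for discarded recordings


def saturation_fraction(rec: SWVRecording) -> float:
    """Mean over frames of the per-frame fraction of near-ceiling pixels.

    A pixel counts as saturated when its velocity exceeds
    ``saturation_velocity_fraction * v_max`` (18 m/s at the defaults).
    """
    thresh = rec.saturation_velocity_fraction * rec.v_max
    maps = rec.maps if rec.roi is None else rec.maps[:, rec.roi]
    per_frame = (maps > thresh).reshape(maps.shape[0], -1).mean(axis=1)
    return float(per_frame.mean())


def qc_recording(rec: SWVRecording) -> SWVSummary:
    """Apply the saturation-discard rule and summarise.

    The rule is strict: a recording fails only when the saturation fraction
    exceeds the 5% threshold, so exactly 5% still passes.  The mean velocity
    pools all pixels of all frames (within the ROI if one is set) and is not
    computed for discarded recordings.
    """
    frac = saturation_fraction(rec)
    passed = frac <= rec.saturation_threshold_fraction
    mean_v = None
    if passed:
        maps = rec.maps if rec.roi is None else rec.maps[:, rec.roi]
        mean_v = float(maps.mean())
    return SWVSummary(
        side=rec.side,
        n_frames=rec.maps.shape[0],
        saturation_fraction=frac,
        passed_qc=passed,
        mean_velocity=mean_v,
    )


def side_mean(medial: SWVSummary, lateral: SWVSummary) -> float | None:
    """Unweighted mean of the medial and lateral side means.

    Undefined (None) when either side failed QC; the participant is then
    flagged missing for the mean-of-sides outcome.
    """
    if not (medial.passed_qc and lateral.passed_qc):
        return None
    return 0.5 * (medial.mean_velocity + lateral.mean_velocity)


def read_recording(path: str | Path, side: str = "lateral", roi: np.ndarray | None = None) -> SWVRecording:
    """Read velocity maps from a multi-frame TIFF (float m/s) or a text matrix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        maps = tifffile.imread(path)
    else:
        maps = np.loadtxt(path)
    return SWVRecording(maps=maps, side=side, roi=roi)
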