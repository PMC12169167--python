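"""Force-elongation curves and tendon stiffness.

Per trial, the synchronised tendon-force and elongation series are paired over
the loading ramp, resampled to 100 points evenly spaced in force, and fitted
with a 2nd-degree polynomial of force as a function of elongation (the
conventional orientation of a tendon force-elongation curve; evaluation at
arbitrary force levels inverts the fitted quadratic on its loading branch
numerically).  Trials whose fit has a
coefficient of determination below 0.90 are excluded.  The included curves of
one participant are standardised to a common force — the lowest included-trial
peak force observed either pre- or post-training — averaged pointwise into a
mean curve, and stiffness is the least-squares straight-line slope dF/de of
that mean curve over 60-100% of the common force, in N/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mechanics import ForceTrace
from .tracking import ElongationSeries

RESAMPLE_N = 100
R2_MIN = 0.90
SLOPE_RANGE = (0.6, 1.0)
ONSET_FRACTION = 0.05  # force onset threshold as a fraction of trial peak


@dataclass(frozen=True)
class ForceElongationTrial:
    """Paired (tendon force, elongation) samples of one loading ramp.

    ``fit`` holds the coefficients (highest power first) of the quadratic
    F(e) fitted to the resampled pairs; ``e_range`` is the elongation span of
    the resampled data, kept for the numeric inversion used when the curve is
    evaluated at arbitrary force levels.
    """

    force: np.ndarray  # N, at frame times, loading phase only
    elongation: np.ndarray  # mm
    fit: np.ndarray | None = None  # polyfit coefficients of F(e), highest first
    e_range: tuple[float, float] | None = None
    r2: float | None = None
    peak_force: float | None = None
    included: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float)
        e = np.asarray(self.elongation, dtype=float)
        if f.shape != e.shape:
            raise ValueError("force and elongation must have equal length")
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "elongation", e)

    def elongation_at(self, force_grid: np.ndarray) -> np.ndarray:
        """Invert the fitted quadratic F(e) on its monotonically loading branch."""
        if self.fit is None:
            raise ValueError("trial has not been fitted")
        lo, hi = self.e_range
        pad = 0.15 * (hi - lo)
        e_dense = np.linspace(lo - pad, hi + pad, 2001)
        f_dense = np.polyval(self.fit, e_dense)
        increasing = np.diff(f_dense) > 0
        if not increasing.all():
            # clip to the longest increasing run (covers the data branch)
            runs = np.flatnonzero(np.diff(np.r_[False, increasing, False]))
            starts, stops = runs[::2], runs[1::2]
            k = np.argmax(stops - starts)
            sl = slice(starts[k], stops[k] + 1)
            e_dense, f_dense = e_dense[sl], f_dense[sl]
        return np.interp(np.asarray(force_grid, dtype=float), f_dense, e_dense)


@dataclass(frozen=True)
class MeanCurve:
    """Participant-level mean force-elongation curve on a common force grid."""

    force_grid: np.ndarray  # N, strictly increasing, 0 -> common_force
    elongation: np.ndarray  # mm
    common_force: float
    n_trials: int

    def __post_init__(self) -> None:
        fg = np.asarray(self.force_grid, dtype=float)
        if np.any(np.diff(fg) <= 0):
            raise ValueError("force grid must be strictly increasing")
        object.__setattr__(self, "force_grid", fg)
        object.__setattr__(self, "elongation", np.asarray(self.elongation, dtype=float))


@dataclass(frozen=True)
class StiffnessResult:
    stiffness: float  # N/mm
    analysis_range: tuple[float, float]  # N
    n_trials_used: int
    monotonic: bool  # elongation strictly increasing over the analysis range


def pair_force_elongation(
    force_trace: ForceTrace,
    elong: ElongationSeries,
    frame_rate: float,
    onset_fraction: float = ONSET_FRACTION,
) -> ForceElongationTrial:
    """Pair tendon force with elongation at frame times over the loading ramp.

    ``force_trace`` must already be filtered and converted to tendon force;
    frame ``t`` is matched to sample ``trigger_index + round(t * rate /
    frame_rate)``.  Pairs are restricted to the monotonically loading phase:
    from force onset (``onset_fraction`` of the trial peak) to the peak
    sample.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n_frames = len(elong.values)
    idx = force_trace.trigger_index + np.rint(
        np.arange(n_frames) * force_trace.rate / frame_rate
    ).astype(int)
    if idx[-1] >= len(force_trace.samples):
        raise ValueError("frames extend past the end of the force record")
    force = force_trace.samples[idx]

    peak_i = int(np.argmax(force))
    peak = force[peak_i]
    if peak <= 0:
        raise ValueError("no positive loading phase in the force record")
    above = np.nonzero(force[: peak_i + 1] >= onset_fraction * peak)[0]
    start_i = int(above[0]) if above.size else 0
    if peak_i - start_i < 1:
        raise ValueError("loading phase too short to pair")
    return ForceElongationTrial(
        force=force[start_i : peak_i + 1],
        elongation=elong.values[start_i : peak_i + 1],
        peak_force=float(peak),
    )


def fit_trial(
    trial: ForceElongationTrial,
    resample_n: int = RESAMPLE_N,
    r2_min: float = R2_MIN,
) -> ForceElongationTrial:
    """Resample a trial evenly in force, fit a quadratic F(e), and gate on R^2.

    The (F, e) pairs are interpolated onto ``resample_n`` force levels evenly
    spaced from 0 to the trial peak (linear extrapolation covers the short
    pre-onset stretch below the first pair), a least-squares quadratic of
    force as a function of elongation is fitted, and R^2 is computed on the
    resampled points.  The trial is included when R^2 >= ``r2_min`` (the
    exclusion rule is strictly "lower than").
    """
    if len(trial.force) < 10:
        raise ValueError("need at least 10 loading-phase pairs to fit")
    order = np.argsort(trial.force, kind="stable")
    f_sorted = trial.force[order]
    e_sorted = trial.elongation[order]
    if f_sorted[-1] - f_sorted[0] <= 0:
        raise ValueError("degenerate trial: constant force")
    grid = np.linspace(0.0, f_sorted[-1], resample_n)
    e_resampled = np.interp(grid, f_sorted, e_sorted)
    below = grid < f_sorted[0]
    if below.any() and f_sorted[1] > f_sorted[0]:
        slope0 = (e_sorted[1] - e_sorted[0]) / (f_sorted[1] - f_sorted[0])
        e_resampled[below] = e_sorted[0] + slope0 * (grid[below] - f_sorted[0])

    coeffs = np.polyfit(e_resampled, grid, 2)
    pred = np.polyval(coeffs, e_resampled)
    ss_res = float(np.sum((grid - pred) ** 2))
    ss_tot = float(np.sum((grid - grid.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    return replace(
        trial,
        fit=coeffs,
        e_range=(float(e_resampled.min()), float(e_resampled.max())),
        r2=r2,
        peak_force=float(f_sorted[-1]),
        included=r2 >= r2_min,
    )


def common_force(peaks_pre: list[float], peaks_post: list[float]) -> float:
    """Lowest included-trial peak force across a participant's two sessions."""
    if not peaks_pre or not peaks_post:
        raise ValueError("both sessions need at least one included trial")
    return float(min(min(peaks_pre), min(peaks_post)))


def mean_curve(trials: list[ForceElongationTrial], common_force: float, n_points: int = RESAMPLE_N) -> MeanCurve:
    """Average the included fitted trials on a 0 -> common_force grid."""
    used = [t for t in trials if t.included]
    if not used:
        raise ValueError("no included trials to average")
    if common_force <= 0:
        raise ValueError("common force must be positive")
    grid = np.linspace(0.0, common_force, n_points)
    grid[0] = 0.0
    stack = np.vstack([t.elongation_at(grid) for t in used])
    # the grid must be strictly increasing; linspace guarantees it for n>=2
    return MeanCurve(force_grid=grid, elongation=stack.mean(axis=0), common_force=common_force, n_trials=len(used))


def stiffness_slope(curve: MeanCurve, slope_range: tuple[float, float] = SLOPE_RANGE) -> StiffnessResult:
    """Stiffness = OLS slope dF/de of the mean curve over 60-100% force.

    Regresses force on elongation over the grid points whose force lies in
    ``[slope_range[0], slope_range[1]] * common_force`` (an ordinary
    least-squares line over all ~40 points, not a two-point difference).
    Non-monotonic elongation over the range is flagged.
    """
    lo = slope_range[0] * curve.common_force
    hi = slope_range[1] * curve.common_force
    mask = (curve.force_grid >= lo - 1e-9) & (curve.force_grid <= hi + 1e-9)
    f = curve.force_grid[mask]
    e = curve.elongation[mask]
    if f.size < 2:
        raise ValueError("fewer than 2 grid points in the analysis range")
    monotonic = bool(np.all(np.diff(e) > 0))
    slope = float(np.polyfit(e, f, 1)[0])
    return StiffnessResult(
        stiffness=slope,
        analysis_range=(float(lo), float(hi)),
        n_trials_used=curve.n_trials,
        monotonic=monotonic,
    )
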