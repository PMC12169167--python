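"""Sub-pixel landmark tracking with a pyramidal Lucas-Kanade tracker.

Tendon elongation is measured as the change in distance between two anatomical
landmarks visible in the sagittal B-mode scan: the patella apex and the tibial
plateau.  Each landmark is tracked frame-to-frame with an iterative
Lucas-Kanade optical-flow solver: within a local window the displacement ``d``
between consecutive frames minimises ``sum_w (J(x + d) - I(x))^2``, solved by
Gauss-Newton steps ``d += G^{-1} b`` where ``G`` is the structure tensor of the
spatial gradients and ``b`` the gradient-weighted temporal difference.  A
coarse-to-fine image pyramid extends the linearisation range to displacements
of several pixels per frame.

Displacements accumulate frame-to-frame (rather than being re-anchored to
frame 0), which matches the frame-to-frame definition of the elongation
measurement; the trade-off is that tracking noise can drift over very long
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class FrameSequence:
    """Grayscale ultrasound frame stack.

    ``frames`` has shape (n_frames, rows, cols); ``pixel_scale`` is mm/pixel.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_scale: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("frames must be a (n>=2, rows, cols) stack")
        if self.frame_rate <= 0 or self.pixel_scale <= 0:
            raise ValueError("frame_rate and pixel_scale must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class LandmarkTrack:
    """Per-frame sub-pixel landmark positions (x, y) and convergence flags."""

    positions: np.ndarray  # (n_frames, 2) as (x, y), 0-based pixel coordinates
    status: np.ndarray  # (n_frames,) bool, True where tracking converged

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        st = np.asarray(self.status, dtype=bool)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] != st.shape[0]:
            raise ValueError("positions must be (n, 2) with matching status")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "status", st)


@dataclass(frozen=True)
class ElongationSeries:
    """Tendon elongation in mm per frame, zero-referenced to frame 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0 or abs(vals[0]) > 1e-12:
            raise ValueError("elongation must start at 0 at frame 0")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class LKParams:
    """Tracker settings.

    window : odd window side length in pixels.
    pyramid_levels : number of pyramid levels (1 = no pyramid).
    max_iter : Gauss-Newton iterations per level.
    tol : convergence threshold on the update step, pixels.
    smooth_sigma : Gaussian pre-smoothing of each frame, pixels.
    min_eig : structure-tensor eigenvalue floor (per pixel) below which the
        window is considered textureless and the track is flagged.
    """

    window: int = 21
    pyramid_levels: int = 3
    max_iter: int = 30
    tol: float = 0.01
    smooth_sigma: float = 1.0
    min_eig: float = 1e-6

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.pyramid_levels < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid LK parameters")


def _build_pyramid(frame: np.ndarray, levels: int, sigma: float) -> list[np.ndarray]:
    """Smoothed, spline-prefiltered pyramid; level 0 at full resolution.

    Each level is stored as cubic-spline coefficients so that sub-pixel window
    sampling (and hence the gradient estimates) is smooth — bilinear sampling
    has piecewise-constant derivatives that bias the sub-pixel solution.
    """
    smoothed = [ndimage.gaussian_filter(frame, sigma, mode="nearest")]
    for _ in range(1, levels):
        prev = smoothed[-1]
        if min(prev.shape) < 8:
            break
        smoothed.append(ndimage.gaussian_filter(prev, 1.0, mode="nearest")[::2, ::2])
    return [ndimage.spline_filter(lev, order=3, mode="nearest") for lev in smoothed]


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=3, prefilter=False, mode="nearest")


def _lk_step(
    img_prev: np.ndarray,
    img_next: np.ndarray,
    point: np.ndarray,
    guess: np.ndarray,
    params: LKParams,
) -> tuple[np.ndarray, bool]:
    """One-level iterative LK displacement estimate for one point.

    Returns (displacement, converged).  ``point`` is (x, y) in this level's
    coordinates; ``guess`` is the initial displacement.
    """
    half = params.window // 2
    off = np.arange(-half, half + 1, dtype=float)
    ox, oy = np.meshgrid(off, off)
    xs = point[0] + ox.ravel()
    ys = point[1] + oy.ravel()

    template = _sample(img_prev, xs, ys)
    # spatial gradients of the template window, central differences
    gx = (_sample(img_prev, xs + 1, ys) - _sample(img_prev, xs - 1, ys)) / 2.0
    gy = (_sample(img_prev, xs, ys + 1) - _sample(img_prev, xs, ys - 1)) / 2.0

    g_xx = float(np.dot(gx, gx))
    g_xy = float(np.dot(gx, gy))
    g_yy = float(np.dot(gy, gy))
    trace = g_xx + g_yy
    det = g_xx * g_yy - g_xy * g_xy
    # smaller eigenvalue of the 2x2 structure tensor
    lam_min = trace / 2.0 - np.sqrt(max(trace * trace / 4.0 - det, 0.0))
    if lam_min < params.min_eig * off.size:
        return guess, False

    d = guess.astype(float).copy()
    for _ in range(params.max_iter):
        moved = _sample(img_next, xs + d[0], ys + d[1])
        err = template - moved
        b = np.array([np.dot(gx, err), np.dot(gy, err)])
        try:
            step = np.linalg.solve(np.array([[g_xx, g_xy], [g_xy, g_yy]]), b)
        except np.linalg.LinAlgError:
            return d, False
        d += step
        if np.hypot(step[0], step[1]) < params.tol:
            return d, True
    return d, False


def track_landmark(
    seq: FrameSequence,
    init: tuple[float, float],
    params: LKParams | None = None,
) -> LandmarkTrack:
    """Track a single landmark through a frame sequence.

    ``init`` is the (x, y) position in frame 0, 0-based pixel coordinates
    (x rightward, y downward).  Displacements are estimated between each pair
    of consecutive frames and accumulated.  Frames where the local window is
    textureless or the iteration fails to converge are flagged ``False`` in
    ``status`` and the position is carried forward unchanged.
    """
    params = params or LKParams()
    frames = seq.frames
    rows, cols = seq.shape
    half = params.window // 2
    x0, y0 = float(init[0]), float(init[1])
    if not (half <= x0 <= cols - 1 - half and half <= y0 <= rows - 1 - half):
        raise ValueError(
            f"initial position {init} too close to the image border for a "
            f"{params.window}-pixel window"
        )

    n = seq.n_frames
    positions = np.empty((n, 2))
    status = np.ones(n, dtype=bool)
    positions[0] = (x0, y0)

    pyr_prev = _build_pyramid(frames[0], params.pyramid_levels, params.smooth_sigma)
    for t in range(1, n):
        pyr_next = _build_pyramid(frames[t], params.pyramid_levels, params.smooth_sigma)
        levels = min(len(pyr_prev), len(pyr_next))
        point = positions[t - 1]
        d = np.zeros(2)
        ok = True
        for lev in range(levels - 1, -1, -1):
            scale = 2.0**lev
            d, ok = _lk_step(pyr_prev[lev], pyr_next[lev], point / scale, d, params)
            if lev > 0:
                d = d * 2.0
        new_pos = point + d
        in_bounds = 0 <= new_pos[0] <= cols - 1 and 0 <= new_pos[1] <= rows - 1
        if ok and in_bounds:
            positions[t] = new_pos
        else:
            positions[t] = point  # carry forward
            status[t] = False
        pyr_prev = pyr_next
    return LandmarkTrack(positions=positions, status=status)


def elongation_from_tracks(
    apex: LandmarkTrack, plateau: LandmarkTrack, pixel_scale: float
) -> ElongationSeries:
    """Inter-landmark distance change in mm, zero-referenced to frame 0.

    ``value[t] = (||apex[t] - plateau[t]|| - ||apex[0] - plateau[0]||) * pixel_scale``.
    Rigid whole-image translation leaves the series unchanged.
    """
    if len(apex.positions) != len(plateau.positions):
        raise ValueError("apex and plateau tracks must have equal length")
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    dist = np.linalg.norm(apex.positions - plateau.positions, axis=1)
    return ElongationSeries(values=(dist - dist[0]) * pixel_scale)


def track_pair_elongation(
    seq: FrameSequence,
    apex_init: tuple[float, float],
    plateau_init: tuple[float, float],
    params: LKParams | None = None,
) -> tuple[ElongationSeries, LandmarkTrack, LandmarkTrack]:
    """Track both landmarks and return elongation plus the raw tracks."""
    apex = track_landmark(seq, apex_init, params)
    plateau = track_landmark(seq, plateau_init, params)
    elong = elongation_from_tracks(apex, plateau, seq.pixel_scale)
    return elong, apex, plateau
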