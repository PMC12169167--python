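"""Synthetic generators for every input the pipeline consumes.

The study protocol is emulated end-to-end with known ground truth:

* a ramped isometric knee-extension trial — the knee moment rises linearly at
  ~70 N*m/s to a peak, sampled at 1,000 Hz with additive sensor noise;
* a speckle-textured B-mode frame stack in which the patella-apex landmark
  separates from the static tibial-plateau landmark according to a prescribed
  quadratic force-elongation law F = a*e^2 + b*e (e in mm);
* shear-wave-velocity pixel maps with a controllable fraction of saturated
  pixels;
* pre/post cohort tables with subject random effects, a training main effect
  and an optional group x training interaction.

Noise-free generation is exactly invertible: the downstream pipeline recovers
the programmed elongation law and cohort effects to numerical precision, which
is what the recovery tests exercise.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .mechanics import ForceTrace, MomentArms
from .swv import SWVRecording
from .tracking import FrameSequence, LandmarkTrack


@dataclass(frozen=True)
class TrialSpec:
    """One synthetic ramped-contraction trial.

    The true force-elongation law is ``F = a*e^2 + b*e`` with ``a`` in N/mm^2
    and ``b`` in N/mm (monotonically stiffening, invertible for F >= 0).
    Image geometry: the plateau landmark sits at ``plateau_xy`` and is static
    up to an optional rigid whole-image drift; the apex landmark starts at
    ``apex_xy`` and moves along +x so that the inter-landmark distance equals
    the rest distance plus ``e(F(t))``.
    """

    peak_moment: float = 150.0  # N*m
    moment_ramp_rate: float = 70.0  # N*m/s
    external_arm: float = 0.40  # m
    internal_arm: float = 0.0355  # m
    curve_a: float = 200.0  # N/mm^2
    curve_b: float = 500.0  # N/mm
    frame_rate: float = 50.0  # Hz
    force_rate: float = 1000.0  # Hz
    pixel_scale: float = 0.1  # mm/pixel
    noise_force_sd: float = 5.0  # N, at the cuff sensor
    noise_image_sd: float = 0.02  # intensity units on a ~[0, 1] image
    image_shape: tuple[int, int] = (96, 384)  # rows, cols
    plateau_xy: tuple[float, float] = (60.0, 48.0)
    apex_xy: tuple[float, float] = (300.0, 48.0)
    rigid_drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    pretrigger_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_moment <= 0 or self.moment_ramp_rate <= 0:
            raise ValueError("peak moment and ramp rate must be positive")
        if self.frame_rate <= 0 or self.force_rate <= 0:
            raise ValueError("rates must be positive")
        if self.curve_a < 0 or self.curve_b <= 0:
            raise ValueError("curve must have a >= 0 and b > 0")
        if self.noise_force_sd < 0 or self.noise_image_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def arms(self) -> MomentArms:
        return MomentArms(external_arm=self.external_arm, internal_arm=self.internal_arm)

    @property
    def peak_tendon_force(self) -> float:
        return self.peak_moment / self.internal_arm

    def elongation_at(self, tendon_force: np.ndarray | float) -> np.ndarray | float:
        """Invert the true curve: e(F) in mm for tendon force F in N."""
        f = np.asarray(tendon_force, dtype=float)
        f = np.maximum(f, 0.0)
        a, b = self.curve_a, self.curve_b
        if a == 0:
            e = f / b
        else:
            e = (-b + np.sqrt(b * b + 4.0 * a * f)) / (2.0 * a)
        return e if e.ndim else float(e)

    def true_stiffness(self, common_force: float, lo_frac: float = 0.6) -> float:
        """Analytic least-squares slope dF/de over [lo_frac, 1] x common_force.

        Dense-grid evaluation of the true curve; used as ground truth for
        recovery tests.
        """
        f = np.linspace(lo_frac * common_force, common_force, 20001)
        e = np.asarray(self.elongation_at(f))
        slope = np.polyfit(e, f, 1)[0]
        return float(slope)


def generate_force_trace(spec: TrialSpec) -> ForceTrace:
    """Cuff-force trace for a ramped trial.

    A quiet pre-trigger baseline is followed by a linear moment ramp at
    ``moment_ramp_rate`` up to ``peak_moment``; the trace ends at the peak.
    Gaussian sensor noise of SD ``noise_force_sd`` is added throughout.  The
    trigger index (frame 0) marks the ramp onset.
    """
    rng = np.random.default_rng(spec.seed)
    n_pre = int(round(spec.pretrigger_s * spec.force_rate))
    ramp_duration = spec.peak_moment / spec.moment_ramp_rate
    n_ramp = int(round(ramp_duration * spec.force_rate))
    t_ramp = np.arange(n_ramp + 1) / spec.force_rate
    moment = np.minimum(spec.moment_ramp_rate * t_ramp, spec.peak_moment)
    force = np.concatenate([np.zeros(n_pre), moment / spec.external_arm])
    force = force + rng.normal(0.0, spec.noise_force_sd, size=force.size)
    return ForceTrace(samples=force, rate=spec.force_rate, trigger_index=n_pre)


def _reference_image(spec: TrialSpec, rng: np.random.Generator) -> np.ndarray:
    """Speckle background plus two bright Gaussian landmark blobs."""
    rows, cols = spec.image_shape
    speckle = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 1.5)
    speckle = 0.5 + 0.15 * speckle / speckle.std()
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    img = speckle
    for cx, cy in (spec.plateau_xy, spec.apex_xy):
        img = img + 1.0 * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 2.5**2)))
    return img


def _tendon_warp_sources(
    x_dest: np.ndarray, x_plateau: float, x_apex: float, delta: float, rigid_radius: float = 16.0
) -> np.ndarray:
    """Inverse warp of the 1-D tendon stretch along x.

    The bony landmarks move rigidly: pixels within ``rigid_radius`` of the
    plateau (and everything to its left) stay fixed, pixels within the radius
    of the displaced apex (and everything to its right) translate by
    ``delta``, and only the tendon tissue in between stretches linearly.
    """
    knots_dest = np.array([x_plateau + rigid_radius, x_apex + delta - rigid_radius])
    knots_src = np.array([x_plateau + rigid_radius, x_apex - rigid_radius])
    lo, hi = x_dest.min() - 1.0, x_dest.max() + 1.0
    xd = np.concatenate([[lo], knots_dest, [hi]])
    xs = np.concatenate([[lo], knots_src, [hi - delta]])
    return np.interp(x_dest, xd, xs)


def generate_frame_sequence(
    spec: TrialSpec, force: ForceTrace
) -> tuple[FrameSequence, LandmarkTrack, LandmarkTrack]:
    """Render the frame stack for a trial and return it with ground truth.

    The tissue follows the supplied force trace: at frame ``t`` (sampled from
    the trace at the synchronised sample index) the inter-landmark distance is
    the rest distance plus ``e(F_tendon(t))`` from the trial's true curve.
    Sub-pixel motion is realised by warping a fixed reference speckle image
    with cubic-spline interpolation; sensor noise is added after warping so
    that it does not move with the tissue.

    Returns ``(sequence, apex_truth, plateau_truth)``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows, cols = spec.image_shape
    ref = _reference_image(spec, rng)
    ref_spline = ndimage.spline_filter(ref, order=3, mode="nearest")

    step = force.rate / spec.frame_rate
    n_frames = int((len(force.samples) - 1 - force.trigger_index) / step) + 1
    if n_frames < 2:
        raise ValueError("force trace does not cover at least two frames")
    idx = force.trigger_index + np.rint(np.arange(n_frames) * step).astype(int)
    tendon_f = force.samples[idx] * spec.external_arm / spec.internal_arm
    elong_mm = np.asarray(spec.elongation_at(tendon_f))
    elong_mm = elong_mm - elong_mm[0]  # distance change is referenced to frame 0
    delta_px = elong_mm / spec.pixel_scale

    x_p, y_p = spec.plateau_xy
    x_a, y_a = spec.apex_xy
    drift = np.outer(np.arange(n_frames), np.asarray(spec.rigid_drift_px_per_frame, dtype=float))
    margin = 12  # keep a tracking window inside the image
    apex_x = x_a + delta_px + drift[:, 0]
    xs_all = np.concatenate([apex_x, x_p + drift[:, 0]])
    ys_all = np.concatenate([y_a + drift[:, 1], y_p + drift[:, 1]])
    if (xs_all.min() < margin or xs_all.max() > cols - 1 - margin
            or ys_all.min() < margin or ys_all.max() > rows - 1 - margin):
        raise ValueError("peak elongation or drift pushes a landmark outside the image")

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    frames = np.empty((n_frames, rows, cols))
    for t in range(n_frames):
        dx, dy = drift[t]
        src_x = _tendon_warp_sources(xx[0] - dx, x_p, x_a, float(delta_px[t]))
        src_y = yy[:, 0] - dy
        coords_y, coords_x = np.meshgrid(src_y, src_x, indexing="ij")
        frame = ndimage.map_coordinates(
            ref_spline, [coords_y, coords_x], order=3, prefilter=False, mode="nearest"
        )
        if spec.noise_image_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_image_sd, size=frame.shape)
        frames[t] = frame

    apex_truth = np.column_stack([x_a + delta_px + drift[:, 0], np.full(n_frames, y_a) + drift[:, 1]])
    plateau_truth = np.column_stack([np.full(n_frames, x_p) + drift[:, 0], np.full(n_frames, y_p) + drift[:, 1]])
    ok = np.ones(n_frames, dtype=bool)
    seq = FrameSequence(frames=frames, frame_rate=spec.frame_rate, pixel_scale=spec.pixel_scale)
    return seq, LandmarkTrack(apex_truth, ok), LandmarkTrack(plateau_truth, ok)


def generate_swv_map(
    shape: tuple[int, int],
    base_velocity: float,
    saturated_fraction: float,
    n_frames: int = 5,
    seed: int = 0,
    sd: float = 1.0,
    v_max: float = 20.0,
    side: str = "lateral",
) -> SWVRecording:
    """Shear-wave-velocity pixel maps with a programmed saturation level.

    Pixel velocities are Normal(base_velocity, sd) clipped to [0, v_max];
    in every frame exactly ``round(saturated_fraction * n_pixels)`` pixels are
    forced above 0.9 * v_max.
    """
    if base_velocity < 0:
        raise ValueError("base_velocity must be non-negative")
    if not 0.0 <= saturated_fraction <= 1.0:
        raise ValueError("saturated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pix = int(np.prod(shape))
    n_sat = int(round(saturated_fraction * n_pix))
    maps = np.empty((n_frames,) + tuple(shape))
    for t in range(n_frames):
        vals = np.clip(rng.normal(base_velocity, sd, size=n_pix), 0.0, v_max)
        if n_sat:
            sat_idx = rng.choice(n_pix, size=n_sat, replace=False)
            vals[sat_idx] = rng.uniform(0.925 * v_max, 0.995 * v_max, size=n_sat)
        maps[t] = vals.reshape(shape)
    return SWVRecording(maps=maps, side=side, v_max=v_max)


@dataclass(frozen=True)
class CohortSpec:
    """Pre/post cohort with a between-subject group factor (OC vs NOC).

    ``outcome = mu_baseline + subject + post*(training_effect +
    is_OC*interaction_effect) + location_offset + residual`` with
    subject ~ N(0, sd_between) and residual ~ N(0, sd_within) per cell.
    """

    n_per_group: tuple[int, int] = (15, 17)  # (OC, NOC)
    mu_baseline: float = 100.0
    sd_between: float = 10.0
    training_effect: float = 0.0
    interaction_effect: float = 0.0
    sd_within: float = 5.0
    n_locations: int = 1
    location_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 participants per group")
        if self.sd_between < 0 or self.sd_within < 0:
            raise ValueError("SDs must be non-negative")
        if self.n_locations not in (1, 3):
            raise ValueError("n_locations must be 1 or 3")


def cohort_arrays(spec: CohortSpec, rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Numeric core of the cohort model.

    Returns ``(group_codes, y)`` with ``group_codes`` 0 for OC and 1 for NOC,
    and ``y`` of shape (n_subjects, 2 times, n_locations): the model is
    ``mu + subject + post*(training + is_OC*interaction) + location_offset +
    residual``.  Used directly by the type-I-error/power simulations so that
    they exercise exactly the model the table generator writes.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_oc, n_noc = spec.n_per_group
    n = n_oc + n_noc
    L = spec.n_locations
    codes = np.repeat([0, 1], [n_oc, n_noc])
    subj = rng.normal(0.0, spec.sd_between, size=n)
    resid = rng.normal(0.0, spec.sd_within, size=(n, 2, L))
    shift = spec.training_effect + (codes == 0) * spec.interaction_effect
    y = (
        spec.mu_baseline
        + subj[:, None, None]
        + shift[:, None, None] * np.array([0.0, 1.0])[None, :, None]
        + np.asarray(spec.location_offsets[:L])[None, None, :]
        + resid
    )
    return codes, y


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Long-format cohort table: participant, group, time[, location], outcome."""
    codes, y = cohort_arrays(spec)
    locations = ["proximal", "mid", "distal"][: spec.n_locations]
    rows = []
    for i in range(y.shape[0]):
        pid = f"P{i + 1:03d}"
        grp = "OC" if codes[i] == 0 else "NOC"
        for t, time in enumerate(("pre", "post")):
            for j, loc in enumerate(locations):
                row = {"participant": pid, "group": grp, "time": time, "outcome": y[i, t, j]}
                if spec.n_locations > 1:
                    row["location"] = loc
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study synthesis: everything `tendonmech run-all` consumes, on disk.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySpec:
    """A small synthetic training study written to disk with ground truth.

    Each participant gets a subject-specific quadratic force-elongation curve;
    training scales the whole curve F(e) by ``1 + training_gain`` (optionally
    plus an OC-group interaction), so true post-training stiffness is exactly
    ``1 + gain`` times the pre value at a fixed common force.  Per session, ``trials_per_session`` ramp trials are generated,
    plus SWV recordings on both sides, three-site CSA values and MVC attempts.
    """

    n_per_group: tuple[int, int] = (3, 3)
    trials_per_session: int = 2
    training_gain: float = 0.20
    interaction_gain: float = 0.0
    curve_b_mean: float = 500.0
    curve_b_sd: float = 50.0
    curve_a: float = 200.0
    peak_moment_mean: float = 140.0
    peak_moment_sd: float = 10.0
    frame_rate: float = 25.0
    noise_force_sd: float = 5.0
    noise_image_sd: float = 0.02
    swv_base: float = 7.0
    swv_training_effect: float = 1.2
    csa_mean: float = 72.0
    csa_training_effect: float = 0.8
    seed: int = 0


def generate_study(spec: StudySpec, out_dir: str | Path) -> Path:
    """Write a complete synthetic study directory.

    Layout::

        participants.tsv                  id, group, moment arms
        csa.tsv / mvc.tsv                 morphology and strength inputs
        trials/<pid>_<sess>_t<k>_force.txt    time_s, force_N
        trials/<pid>_<sess>_t<k>_frames.tif   grayscale frame stack
        trials/<pid>_<sess>_t<k>_meta.json    landmark seeds + ground truth
        swv/<pid>_<sess>_<side>.tif       velocity maps, float32 m/s
        truth.json                        per-participant generating curves
    """
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    (out / "swv").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    groups = ["OC"] * spec.n_per_group[0] + ["NOC"] * spec.n_per_group[1]
    participants, csa_rows, mvc_rows = [], [], []
    truth: dict[str, dict] = {}
    for i, grp in enumerate(groups):
        pid = f"P{i + 1:03d}"
        internal = rng.normal(0.0355, 0.002)
        external = rng.normal(0.40, 0.02)
        participants.append(
            {"participant": pid, "group": grp, "external_arm_m": round(external, 4), "internal_arm_m": round(internal, 4)}
        )
        b_pre = rng.normal(spec.curve_b_mean, spec.curve_b_sd)
        gain = spec.training_gain + (grp == "OC") * spec.interaction_gain
        peak_moment = rng.normal(spec.peak_moment_mean, spec.peak_moment_sd)
        truth[pid] = {
            "a_pre": spec.curve_a, "b_pre": b_pre,
            "a_post": spec.curve_a * (1.0 + gain), "b_post": b_pre * (1.0 + gain),
            "peak_moment": peak_moment,
        }

        for sess, scale in (("pre", 1.0), ("post", 1.0 + gain)):
            for k in range(spec.trials_per_session):
                tspec = TrialSpec(
                    peak_moment=peak_moment * float(rng.uniform(0.95, 1.0)),
                    external_arm=external,
                    internal_arm=internal,
                    curve_a=spec.curve_a * scale,
                    curve_b=b_pre * scale,
                    frame_rate=spec.frame_rate,
                    noise_force_sd=spec.noise_force_sd,
                    noise_image_sd=spec.noise_image_sd,
                    seed=int(rng.integers(2**31 - 1)),
                )
                write_trial(tspec, out / "trials", f"{pid}_{sess}_t{k + 1}")
            for side in ("medial", "lateral"):
                base = spec.swv_base + (sess == "post") * spec.swv_training_effect + rng.normal(0, 0.3)
                rec = generate_swv_map(
                    (64, 64), base_velocity=max(base, 0.5), saturated_fraction=0.0,
                    n_frames=4, seed=int(rng.integers(2**31 - 1)), side=side,
                )
                tifffile.imwrite(out / "swv" / f"{pid}_{sess}_{side}.tif", rec.maps.astype(np.float32),
                                 photometric="minisblack")
            for j, loc in enumerate(("proximal", "mid", "distal")):
                csa = spec.csa_mean + 2.0 * (1 - j) + (sess == "post") * spec.csa_training_effect + rng.normal(0, 0.5)
                csa_rows.append({"participant": pid, "session": sess, "location": loc, "csa_mm2": round(csa, 3)})
            for attempt in range(1, 4):
                mvc_rows.append(
                    {"participant": pid, "session": sess, "attempt": attempt,
                     "moment_nm": round(peak_moment * float(rng.uniform(0.92, 1.02)), 2)}
                )

    pd.DataFrame(participants).to_csv(out / "participants.tsv", sep="\t", index=False)
    pd.DataFrame(csa_rows).to_csv(out / "csa.tsv", sep="\t", index=False)
    pd.DataFrame(mvc_rows).to_csv(out / "mvc.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out


def write_trial(spec: TrialSpec, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write one trial: force text file, frame TIFF and a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    force = generate_force_trace(spec)
    seq, apex, plateau = generate_frame_sequence(spec, force)

    force_path = out_dir / f"{stem}_force.txt"
    np.savetxt(
        force_path,
        np.column_stack([force.times, force.samples]),
        fmt="%.6f",
        header="time_s force_N",
        comments="# ",
    )
    frames_path = out_dir / f"{stem}_frames.tif"
    tifffile.imwrite(frames_path, seq.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "stem": stem,
        "frame_rate": spec.frame_rate,
        "force_rate": spec.force_rate,
        "pixel_scale": spec.pixel_scale,
        "trigger_index": force.trigger_index,
        "apex_init": list(apex.positions[0]),
        "plateau_init": list(plateau.positions[0]),
        "external_arm_m": spec.external_arm,
        "internal_arm_m": spec.internal_arm,
        "truth": {
            "curve_a": spec.curve_a,
            "curve_b": spec.curve_b,
            "peak_tendon_force": spec.peak_tendon_force,
            "elongation_mm": [float(v) for v in
                              (np.linalg.norm(apex.positions - plateau.positions, axis=1)
                               - np.linalg.norm(apex.positions[0] - plateau.positions[0]))
                              * spec.pixel_scale],
        },
    }
    meta_path = out_dir / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return {"force": force_path, "frames": frames_path, "meta": meta_path}
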