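"""Trial -> participant -> cohort orchestration.

Reads a study directory (as written by ``synthgen.generate_study`` or laid
out the same way from real acquisitions), runs mechanics -> tracking ->
stiffness and the SWV QC per session, reduces morphology (mean of the three
CSA sites) and strength (mean of the two highest MVC attempts), and feeds the
per-participant outcomes into the mixed-design statistics.  Every reported
number is traceable to an intermediate file written under
``<out_dir>/audit/``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import mechanics, stats, stiffness, swv, tracking

log = logging.getLogger("tendonmech")

FLOAT_FMT = "%.10g"
SESSIONS = ("pre", "post")


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run; every threshold is recorded in the report."""

    data_dir: str = "study"
    out_dir: str = "results"
    cutoff_hz: float = 30.0
    lk_window: int = 21
    lk_pyramid_levels: int = 3
    lk_max_iter: int = 30
    lk_tol: float = 0.01
    resample_n: int = 100
    r2_min: float = 0.90
    onset_fraction: float = 0.05
    swv_saturation_threshold: float = 0.05
    swv_velocity_fraction: float = 0.90
    seed: int = 0

    @property
    def lk_params(self) -> tracking.LKParams:
        return tracking.LKParams(
            window=self.lk_window,
            pyramid_levels=self.lk_pyramid_levels,
            max_iter=self.lk_max_iter,
            tol=self.lk_tol,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def strength_from_attempts(moments: np.ndarray) -> float:
    """Strength outcome: mean of the two highest MVC attempts, N*m."""
    moments = np.asarray(moments, dtype=float)
    if len(moments) < 2:
        raise ValueError("need at least two MVC attempts")
    return float(np.sort(moments)[-2:].mean())


def mean_csa(site_csas: np.ndarray) -> float:
    """Mean tendon CSA: arithmetic mean of the per-site outlines, mm^2."""
    site_csas = np.asarray(site_csas, dtype=float)
    if site_csas.size == 0:
        raise ValueError("no CSA sites supplied")
    return float(site_csas.mean())


def process_trial(
    config: RunConfig, force_path: Path, frames_path: Path, meta_path: Path
) -> tuple[stiffness.ForceElongationTrial, pd.DataFrame]:
    """One trial: filter force, convert to tendon force, track, pair, fit.

    Returns the fitted trial and a per-frame audit table.
    """
    meta = json.loads(meta_path.read_text())
    t_f = np.loadtxt(force_path)
    trace = mechanics.ForceTrace(
        samples=t_f[:, 1], rate=meta["force_rate"], trigger_index=meta["trigger_index"]
    )
    arms = mechanics.MomentArms(meta["external_arm_m"], meta["internal_arm_m"])
    tendon = mechanics.tendon_force_trace(trace, arms, cutoff=config.cutoff_hz)

    frames = tifffile.imread(frames_path)
    seq = tracking.FrameSequence(
        frames=frames, frame_rate=meta["frame_rate"], pixel_scale=meta["pixel_scale"]
    )
    elong, apex, plateau = tracking.track_pair_elongation(
        seq, tuple(meta["apex_init"]), tuple(meta["plateau_init"]), config.lk_params
    )
    paired = stiffness.pair_force_elongation(
        tendon, elong, meta["frame_rate"], onset_fraction=config.onset_fraction
    )
    fitted = stiffness.fit_trial(paired, resample_n=config.resample_n, r2_min=config.r2_min)
    audit = pd.DataFrame(
        {
            "frame": np.arange(seq.n_frames),
            "x_apex": apex.positions[:, 0],
            "y_apex": apex.positions[:, 1],
            "x_plateau": plateau.positions[:, 0],
            "y_plateau": plateau.positions[:, 1],
            "elongation_mm": elong.values,
        }
    )
    return fitted, audit


def _session_trials(config: RunConfig, trials_dir: Path, pid: str, session: str, audit_dir: Path):
    fitted = []
    for meta_path in sorted(trials_dir.glob(f"{pid}_{session}_t*_meta.json")):
        stem = meta_path.name.removesuffix("_meta.json")
        trial, audit = process_trial(
            config,
            trials_dir / f"{stem}_force.txt",
            trials_dir / f"{stem}_frames.tif",
            meta_path,
        )
        audit.to_csv(audit_dir / f"{stem}_track.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        fitted.append((stem, trial))
    return fitted


def run_participant(config: RunConfig, pid: str) -> dict:
    """All outcomes for one participant: stiffness, SWV, mean CSA, strength."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    audit_dir = out / "audit"
    audit_dir.mkdir(parents=True, exist_ok=True)

    row: dict = {"participant": pid}
    # --- stiffness: trials per session, common force across sessions -------
    per_session: dict[str, list] = {}
    trial_rows = []
    for session in SESSIONS:
        fitted = _session_trials(config, data / "trials", pid, session, audit_dir)
        per_session[session] = fitted
        for stem, t in fitted:
            trial_rows.append(
                {"participant": pid, "session": session, "trial": stem,
                 "peak_force_N": t.peak_force, "r2": t.r2, "included": t.included}
            )
    pd.DataFrame(trial_rows).to_csv(
        audit_dir / f"{pid}_trials.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    included = {s: [t for _, t in per_session[s] if t.included] for s in SESSIONS}
    row["n_trials_total"] = sum(len(v) for v in per_session.values())
    row["n_trials_included"] = sum(len(v) for v in included.values())
    if all(included[s] for s in SESSIONS):
        cf = stiffness.common_force(
            [t.peak_force for t in included["pre"]],
            [t.peak_force for t in included["post"]],
        )
        row["common_force_N"] = cf
        for session in SESSIONS:
            curve = stiffness.mean_curve(included[session], cf, n_points=config.resample_n)
            res = stiffness.stiffness_slope(curve)
            row[f"stiffness_{session}_N_per_mm"] = res.stiffness
    else:
        log.warning("%s: a session has no included trials; stiffness missing", pid)
        row["common_force_N"] = np.nan
        for session in SESSIONS:
            row[f"stiffness_{session}_N_per_mm"] = np.nan

    # --- shear wave velocity ------------------------------------------------
    for session in SESSIONS:
        summaries = {}
        for side in ("medial", "lateral"):
            path = data / "swv" / f"{pid}_{session}_{side}.tif"
            if path.exists():
                rec = swv.read_recording(path, side=side)
                rec = dataclasses.replace(
                    rec,
                    saturation_threshold_fraction=config.swv_saturation_threshold,
                    saturation_velocity_fraction=config.swv_velocity_fraction,
                )
                summaries[side] = swv.qc_recording(rec)
        for side, summ in summaries.items():
            row[f"swv_{session}_{side}"] = summ.mean_velocity if summ.passed_qc else np.nan
        if len(summaries) == 2:
            mean_v = swv.side_mean(summaries["medial"], summaries["lateral"])
            row[f"swv_{session}_mean"] = np.nan if mean_v is None else mean_v
        else:
            row[f"swv_{session}_mean"] = np.nan

    # --- morphology and strength -------------------------------------------
    csa = pd.read_csv(data / "csa.tsv", sep="\t")
    mvc = pd.read_csv(data / "mvc.tsv", sep="\t")
    for session in SESSIONS:
        sites = csa.query("participant == @pid and session == @session")["csa_mm2"]
        row[f"csa_mean_{session}_mm2"] = mean_csa(sites) if len(sites) else np.nan
        attempts = mvc.query("participant == @pid and session == @session")["moment_nm"]
        row[f"strength_{session}_nm"] = (
            strength_from_attempts(attempts) if len(attempts) >= 2 else np.nan
        )
    return row


def _long_table(outcomes: pd.DataFrame, pre_col: str, post_col: str) -> pd.DataFrame:
    rows = []
    for _, r in outcomes.iterrows():
        for session, col in (("pre", pre_col), ("post", post_col)):
            rows.append({"participant": r["participant"], "group": r["group"],
                         "time": session, "outcome": r[col]})
    return pd.DataFrame(rows).dropna(subset=["outcome"])


def run_cohort(config: RunConfig) -> dict[str, Path]:
    """Run every participant, then the cohort-level statistics.

    Writes ``outcomes.tsv`` (one row per participant), tidy ANOVA tables per
    outcome, Bonferroni post hocs for the CSA time x location follow-up, and
    a ``report.txt`` summarising per-outcome n.  Deterministic byte-for-byte
    for a fixed study directory and config.
    """
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants = pd.read_csv(data / "participants.tsv", sep="\t")

    rows = []
    for _, p in participants.iterrows():
        row = run_participant(config, p["participant"])
        row["group"] = p["group"]
        rows.append(row)
    outcomes = pd.DataFrame(rows)
    outcomes = outcomes[["participant", "group"] + [c for c in outcomes.columns
                                                    if c not in ("participant", "group")]]
    written: dict[str, Path] = {}
    outcomes_path = out / "outcomes.tsv"
    outcomes.to_csv(outcomes_path, sep="\t", index=False, float_format=FLOAT_FMT)
    written["outcomes"] = outcomes_path

    report_lines = [f"tendonmech cohort report (seed={config.seed})", ""]
    anova_frames = []
    for outcome, pre_col, post_col in (
        ("stiffness", "stiffness_pre_N_per_mm", "stiffness_post_N_per_mm"),
        ("strength", "strength_pre_nm", "strength_post_nm"),
        ("swv_mean", "swv_pre_mean", "swv_post_mean"),
    ):
        long = _long_table(outcomes, pre_col, post_col)
        try:
            res = stats.mixed_anova_2way(long)
        except ValueError as exc:
            log.warning("%s: ANOVA skipped (%s)", outcome, exc)
            report_lines.append(f"{outcome}: ANOVA skipped ({exc})")
            continue
        res.insert(0, "outcome", outcome)
        anova_frames.append(res)
        n_used = sum(res.attrs["n_per_group"])
        report_lines.append(
            f"{outcome}: n={n_used} ({res.attrs['n_dropped']} dropped), "
            f"training p={res.loc[res.effect == 'time', 'p'].iloc[0]:.4g}, "
            f"interaction p={res.loc[res.effect == 'time:group', 'p'].iloc[0]:.4g}"
        )

    # CSA: three-way with location
    csa = pd.read_csv(data / "csa.tsv", sep="\t").rename(columns={"csa_mm2": "outcome"})
    csa = csa.rename(columns={"session": "time"}).merge(
        participants[["participant", "group"]], on="participant"
    )
    res3 = stats.mixed_anova_3way(csa)
    res3.insert(0, "outcome", "csa")
    anova_frames.append(res3)
    tl_p = res3.loc[res3.effect == "time:location", "p"].iloc[0]
    report_lines.append(
        f"csa: n={sum(res3.attrs['n_per_group'])}, "
        f"training p={res3.loc[res3.effect == 'time', 'p'].iloc[0]:.4g}, "
        f"time:location p={tl_p:.4g}"
    )
    if np.isfinite(tl_p) and tl_p < 0.05:
        posthoc = stats.bonferroni_posthoc(csa, by="location")
        posthoc_path = out / "csa_posthoc.tsv"
        posthoc.to_csv(posthoc_path, sep="\t", index=False, float_format=FLOAT_FMT)
        written["csa_posthoc"] = posthoc_path
        report_lines.append("csa: Bonferroni post hocs written (time x location)")

    anova_path = out / "anova.tsv"
    pd.concat(anova_frames, ignore_index=True).to_csv(
        anova_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    written["anova"] = anova_path

    # baseline group comparison and correlation, as in the study's layer
    base = outcomes.dropna(subset=["stiffness_pre_N_per_mm", "stiffness_post_N_per_mm"])
    extra_lines = []
    oc = base.loc[base.group == "OC", "stiffness_pre_N_per_mm"].to_numpy()
    noc = base.loc[base.group == "NOC", "stiffness_pre_N_per_mm"].to_numpy()
    if len(oc) >= 2 and len(noc) >= 2:
        try:
            t, p = stats.student_t_independent(oc, noc)
            extra_lines.append(f"baseline stiffness OC vs NOC: t={t:.4g}, p={p:.4g}")
        except ValueError as exc:
            extra_lines.append(f"baseline stiffness comparison undefined ({exc})")
    pre = base["stiffness_pre_N_per_mm"].to_numpy()
    change = base["stiffness_post_N_per_mm"].to_numpy() - pre
    if len(pre) >= 3 and np.var(pre) > 0 and np.var(change) > 0:
        r, p = stats.pearson_r(pre, change)
        extra_lines.append(f"baseline stiffness vs change: r={r:.4g}, p={p:.4g}")
    report_lines += [""] + extra_lines + [""]

    report_path = out / "report.txt"
    report_path.write_text("\n".join(report_lines))
    written["report"] = report_path
    return written


def run_all(config: RunConfig) -> dict[str, Path]:
    """Alias for the full cohort run (CLI `run-all`)."""
    return run_cohort(config)
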