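"""Shared test utilities: pipeline drivers and independent oracles.

The oracles here deliberately use different constructions from the library
code they check: ANOVA sums of squares come from nested least-squares model
comparisons (residual-sum drops over growing indicator spans), the ICC oracle
from explicit sum-of-squares loops, and the stiffness oracle from a dense
evaluation of the analytic curve.
"""

from __future__ import annotations

import numpy as np

from tendonmech import mechanics, stiffness as stf, tracking
from tendonmech.synthgen import TrialSpec, generate_force_trace, generate_frame_sequence


# ---------------------------------------------------------------------------
# end-to-end trial driver
# ---------------------------------------------------------------------------

def run_trial(spec: TrialSpec, lk_params: tracking.LKParams | None = None):
    """mechanics -> tracking -> pairing -> fit for one synthetic trial.

    Returns (fitted_trial, elongation_series, truth_elongation_mm).
    """
    force = generate_force_trace(spec)
    seq, apex, plat = generate_frame_sequence(spec, force)
    tendon = mechanics.tendon_force_trace(force, spec.arms)
    elong, a_trk, p_trk = tracking.track_pair_elongation(
        seq, tuple(apex.positions[0]), tuple(plat.positions[0]), lk_params
    )
    truth = (
        np.linalg.norm(apex.positions - plat.positions, axis=1)
        - np.linalg.norm(apex.positions[0] - plat.positions[0])
    ) * spec.pixel_scale
    paired = stf.pair_force_elongation(tendon, elong, spec.frame_rate)
    return stf.fit_trial(paired), elong, truth


# ---------------------------------------------------------------------------
# analytic stiffness oracle
# ---------------------------------------------------------------------------

def dense_slope_oracle(
    a: float, b: float, common_force: float, lo_frac: float = 0.6, n_grid: int = 100
) -> float:
    """OLS slope of F vs e(F) for the analytic curve F = a e^2 + b e.

    Uses the same slope definition as the pipeline — an ordinary
    least-squares line over the grid points of a ``n_grid``-point force grid
    [0, common_force] that fall in the 60-100% window — but evaluates the
    analytic inverse curve directly and computes the slope from the explicit
    covariance formula.
    """
    grid = np.linspace(0.0, common_force, n_grid)
    f = grid[grid >= lo_frac * common_force - 1e-9]
    if a == 0:
        e = f / b
    else:
        e = (-b + np.sqrt(b * b + 4 * a * f)) / (2 * a)
    em = e - e.mean()
    return float(np.dot(em, f - f.mean()) / np.dot(em, em))


# ---------------------------------------------------------------------------
# ICC / TE oracle from explicit mean-squares arithmetic
# ---------------------------------------------------------------------------

def icc31_oracle(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.sum() / table.size
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (table[i].mean() - grand) ** 2
    ms_rows = ss_rows / (n - 1)
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (table[i, j] - table[i].mean() - table[:, j].mean() + grand) ** 2
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


# ---------------------------------------------------------------------------
# ANOVA oracle: nested least-squares model comparisons
# ---------------------------------------------------------------------------

def _indicators(labels) -> np.ndarray:
    labels = [tuple(np.atleast_1d(lab)) for lab in labels]
    uniq = sorted(set(labels))
    out = np.zeros((len(labels), len(uniq)))
    for i, lab in enumerate(labels):
        out[i, uniq.index(lab)] = 1.0
    return out


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.sum((y - design @ beta) ** 2))


def anova2_oracle(y: np.ndarray, codes: np.ndarray) -> dict[str, float]:
    """Sums of squares for the mixed group x time design on (n, 2) data."""
    n, k = y.shape
    flat = y.ravel()
    subj = np.repeat(np.arange(n), k)
    time = np.tile(np.arange(k), n)
    grp = codes[subj]
    spans = {
        "intercept": _indicators(np.zeros_like(subj)),
        "group": _indicators(grp),
        "subject": _indicators(subj),
        "time": np.hstack([_indicators(subj), _indicators(time)]),
        "time:group": np.hstack([_indicators(subj), _indicators(list(zip(grp, time)))]),
        "saturated": _indicators(list(zip(subj, time))),
    }
    names = list(spans)
    rss = [_rss(flat, spans[nm]) for nm in names]
    return {
        "group": rss[0] - rss[1],
        "subjects_within_group": rss[1] - rss[2],
        "time": rss[2] - rss[3],
        "time:group": rss[3] - rss[4],
        "time:subjects_within_group": rss[4] - rss[5],
        "total": float(np.sum((flat - flat.mean()) ** 2)),
    }


def anova3_oracle(y: np.ndarray, codes: np.ndarray) -> dict[str, float]:
    """Sums of squares for the mixed group x time x location design."""
    n, T, L = y.shape
    flat = y.ravel()
    subj = np.repeat(np.arange(n), T * L)
    time = np.tile(np.repeat(np.arange(T), L), n)
    loc = np.tile(np.arange(L), n * T)
    grp = codes[subj]
    I = _indicators
    s = I(subj)
    st = I(list(zip(subj, time)))
    sl = I(list(zip(subj, loc)))
    chain = [
        ("intercept", I(np.zeros_like(subj))),
        ("group", I(grp)),
        ("subject", s),
        ("time", np.hstack([s, I(time)])),
        ("time:group", np.hstack([s, I(list(zip(grp, time)))])),
        ("subject:time", st),
        ("location", np.hstack([st, I(loc)])),
        ("location:group", np.hstack([st, I(list(zip(grp, loc)))])),
        ("subject:location", np.hstack([st, sl])),
        ("time:location", np.hstack([st, sl, I(list(zip(time, loc)))])),
        ("time:location:group", np.hstack([st, sl, I(list(zip(grp, time, loc)))])),
        ("saturated", I(list(zip(subj, time, loc)))),
    ]
    rss = [_rss(flat, d) for _, d in chain]
    return {
        "group": rss[0] - rss[1],
        "subjects_within_group": rss[1] - rss[2],
        "time": rss[2] - rss[3],
        "time:group": rss[3] - rss[4],
        "time:subjects_within_group": rss[4] - rss[5],
        "location": rss[5] - rss[6],
        "location:group": rss[6] - rss[7],
        "location:subjects_within_group": rss[7] - rss[8],
        "time:location": rss[8] - rss[9],
        "time:location:group": rss[9] - rss[10],
        "time:location:subjects_within_group": rss[10] - rss[11],
        "total": float(np.sum((flat - flat.mean()) ** 2)),
    }
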