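"""Inferential layer: mixed-design ANOVAs, post hocs and simple comparisons.

The study design crossed a between-subject factor (group: combined
oral-contraceptive users vs non-users) with within-subject factors: training
time (pre/post) for every outcome, plus measurement location
(proximal/mid/distal) for tendon cross-sectional area.  The mixed ANOVAs are
computed from the classical weighted-cell-means sums-of-squares decomposition
with separate error strata per within-factor combination:

* between stratum:  group        vs subjects-within-group
* time stratum:     time, time x group        vs time x subjects-within-group
* location stratum: location, location x group vs location x subjects-w-g
* joint stratum:    time x location (x group)  vs the three-way residual

With a single between factor and complete within-subject cells the design has
proportional cell frequencies, so this decomposition is orthogonal (sums of
squares add up to the total exactly) and the F tests are exact even with
unequal group sizes.  Partial eta squared is SS_effect / (SS_effect +
SS_error-for-that-stratum).

Sphericity for the 3-level location factor is assumed (no Greenhouse-Geisser
correction by default), and participants with any missing cell are dropped
listwise per outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

def _complete_cases(
    table: pd.DataFrame, within: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Pivot a long table to (subjects x within-cells), dropping incomplete ones.

    Returns (y, group_codes, group_names, n_dropped) where ``y`` has one axis
    per within factor after the subject axis.
    """
    required = {"participant", "group", "outcome", *within}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    levels = {"time": ["pre", "post"], "location": ["proximal", "mid", "distal"]}
    for w in within:
        obs = set(table[w].unique())
        levels[w] = [lv for lv in levels[w] if lv in obs] or sorted(obs)

    wide = table.pivot_table(index=["participant", "group"], columns=within,
                             values="outcome", aggfunc="mean")
    n_cells = int(np.prod([len(levels[w]) for w in within]))
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if complete.shape[1] != n_cells:
        raise ValueError("within-factor cells missing entirely from the table")

    # order columns by the canonical level ordering
    if len(within) == 1:
        cols = [lv for lv in levels[within[0]]]
    else:
        cols = [(t, l) for t in levels[within[0]] for l in levels[within[1]]]
    complete = complete[cols]
    groups = complete.index.get_level_values("group").to_numpy()
    names = sorted(set(groups))
    codes = np.array([names.index(g) for g in groups])
    shape = (len(complete),) + tuple(len(levels[w]) for w in within)
    y = complete.to_numpy().reshape(shape)
    counts = np.bincount(codes, minlength=len(names))
    if len(names) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 complete participants in each group")
    return y, codes, names, n_dropped


def _group_mean(y: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Mean over subjects within each group; y's first axis is subjects."""
    out = np.stack([y[codes == g].mean(axis=0) for g in range(n_groups)])
    return out


def _result_frame(rows: list[dict], zero_variance: bool) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "p", "partial_eta_squared"])
    df.attrs["zero_variance"] = zero_variance
    return df


def _f_row(name, ss, df_eff, ms_err, df_err):
    ms = ss / df_eff
    if ms_err <= 0:
        return {"effect": name, "SS": ss, "df": df_eff, "MS": ms,
                "F": np.nan, "p": np.nan, "partial_eta_squared": np.nan}
    f = ms / ms_err
    p = float(sps.f.sf(f, df_eff, df_err))
    eta = ss / (ss + ms_err * df_err)
    return {"effect": name, "SS": ss, "df": df_eff, "MS": ms, "F": f, "p": p,
            "partial_eta_squared": eta}


def _err_row(name, ss, df_err):
    return {"effect": name, "SS": ss, "df": df_err, "MS": ss / df_err if df_err else np.nan,
            "F": np.nan, "p": np.nan, "partial_eta_squared": np.nan}


# ---------------------------------------------------------------------------
# two-way mixed ANOVA (group between, time within)
# ---------------------------------------------------------------------------

def mixed_anova_2way_arrays(y: np.ndarray, codes: np.ndarray, n_groups: int = 2) -> pd.DataFrame:
    """Decomposition on a (subjects, 2) array; fast path for simulations."""
    n, k = y.shape
    if k != 2:
        raise ValueError("expected exactly two time levels")
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    grp_cell = _group_mean(y, codes, n_groups)  # (G, 2)
    grp_means = grp_cell.mean(axis=1)
    time_means = y.mean(axis=0)

    ss_bs = k * np.sum((subj_means - grand) ** 2)
    ss_group = k * np.sum(counts * (grp_means - grand) ** 2)
    ss_swg = ss_bs - ss_group
    ss_time = n * np.sum((time_means - grand) ** 2)
    ss_int = float(np.sum(counts[:, None] * (grp_cell - grp_means[:, None]
                                             - time_means[None, :] + grand) ** 2))
    resid = y - subj_means[:, None] - grp_cell[codes] + grp_means[codes, None]
    ss_err = float(np.sum(resid**2))

    df_g, df_swg = n_groups - 1, n - n_groups
    df_t, df_err = k - 1, (n - n_groups) * (k - 1)
    ms_swg = ss_swg / df_swg
    ms_err = ss_err / df_err
    rows = [
        _f_row("group", ss_group, df_g, ms_swg, df_swg),
        _err_row("subjects_within_group", ss_swg, df_swg),
        _f_row("time", ss_time, df_t, ms_err, df_err),
        _f_row("time:group", ss_int, df_g * df_t, ms_err, df_err),
        _err_row("time:subjects_within_group", ss_err, df_err),
    ]
    return _result_frame(rows, zero_variance=(ms_swg <= 0 and ms_err <= 0))


def mixed_anova_2way(table: pd.DataFrame) -> pd.DataFrame:
    """Mixed training x group ANOVA from a long cohort table.

    Between factor ``group``, within factor ``time`` (pre/post); incomplete
    participants are excluded listwise (count in ``attrs['n_dropped']``).
    """
    y, codes, names, n_dropped = _complete_cases(table, within=["time"])
    res = mixed_anova_2way_arrays(y, codes, n_groups=len(names))
    res.attrs["n_dropped"] = n_dropped
    res.attrs["groups"] = names
    res.attrs["n_per_group"] = np.bincount(codes).tolist()
    return res


# ---------------------------------------------------------------------------
# three-way mixed ANOVA (group between; time and location within)
# ---------------------------------------------------------------------------

def mixed_anova_3way_arrays(y: np.ndarray, codes: np.ndarray, n_groups: int = 2) -> pd.DataFrame:
    """Decomposition on a (subjects, n_time, n_location) array."""
    n, T, L = y.shape
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    y_g = _group_mean(y, codes, n_groups)  # (G, T, L)
    m_g = y_g.mean(axis=(1, 2))
    y_t = y.mean(axis=(0, 2))
    y_l = y.mean(axis=(0, 1))
    y_gt = y_g.mean(axis=2)
    y_gl = y_g.mean(axis=1)
    y_st = y.mean(axis=2)
    y_sl = y.mean(axis=1)
    y_tl = y.mean(axis=0)

    ss_bs = T * L * np.sum((m_s - grand) ** 2)
    ss_group = T * L * np.sum(counts * (m_g - grand) ** 2)
    ss_swg = ss_bs - ss_group

    ss_time = n * L * np.sum((y_t - grand) ** 2)
    ss_tg = L * np.sum(counts[:, None] * (y_gt - m_g[:, None] - y_t[None, :] + grand) ** 2)
    dev_t_swg = y_st - m_s[:, None] - y_gt[codes] + m_g[codes, None]
    ss_t_swg = L * np.sum(dev_t_swg**2)

    ss_loc = n * T * np.sum((y_l - grand) ** 2)
    ss_lg = T * np.sum(counts[:, None] * (y_gl - m_g[:, None] - y_l[None, :] + grand) ** 2)
    dev_l_swg = y_sl - m_s[:, None] - y_gl[codes] + m_g[codes, None]
    ss_l_swg = T * np.sum(dev_l_swg**2)

    ss_tl = n * np.sum((y_tl - y_t[:, None] - y_l[None, :] + grand) ** 2)
    dev_tlg = (y_g - y_gt[:, :, None] - y_gl[:, None, :] - y_tl[None]
               + m_g[:, None, None] + y_t[None, :, None] + y_l[None, None, :] - grand)
    ss_tlg = float(np.sum(counts[:, None, None] * dev_tlg**2))
    resid = (y - y_st[:, :, None] - y_sl[:, None, :] + m_s[:, None, None]
             - y_g[codes] + y_gt[codes][:, :, None] + y_gl[codes][:, None, :] - m_g[codes][:, None, None])
    ss_resid = float(np.sum(resid**2))

    df_g, df_swg = n_groups - 1, n - n_groups
    df_t, df_l = T - 1, L - 1
    df_t_swg = df_swg * df_t
    df_l_swg = df_swg * df_l
    df_resid = df_swg * df_t * df_l
    ms_swg = ss_swg / df_swg
    ms_t_swg = ss_t_swg / df_t_swg
    ms_l_swg = ss_l_swg / df_l_swg
    ms_resid = ss_resid / df_resid
    rows = [
        _f_row("group", ss_group, df_g, ms_swg, df_swg),
        _err_row("subjects_within_group", ss_swg, df_swg),
        _f_row("time", ss_time, df_t, ms_t_swg, df_t_swg),
        _f_row("time:group", ss_tg, df_t * df_g, ms_t_swg, df_t_swg),
        _err_row("time:subjects_within_group", ss_t_swg, df_t_swg),
        _f_row("location", ss_loc, df_l, ms_l_swg, df_l_swg),
        _f_row("location:group", ss_lg, df_l * df_g, ms_l_swg, df_l_swg),
        _err_row("location:subjects_within_group", ss_l_swg, df_l_swg),
        _f_row("time:location", ss_tl, df_t * df_l, ms_resid, df_resid),
        _f_row("time:location:group", ss_tlg, df_t * df_l * df_g, ms_resid, df_resid),
        _err_row("time:location:subjects_within_group", ss_resid, df_resid),
    ]
    return _result_frame(rows, zero_variance=(ms_swg <= 0 and ms_resid <= 0))


def mixed_anova_3way(table: pd.DataFrame) -> pd.DataFrame:
    """Mixed training x group x location ANOVA from a long cohort table."""
    y, codes, names, n_dropped = _complete_cases(table, within=["time", "location"])
    res = mixed_anova_3way_arrays(y, codes, n_groups=len(names))
    res.attrs["n_dropped"] = n_dropped
    res.attrs["groups"] = names
    res.attrs["n_per_group"] = np.bincount(codes).tolist()
    return res


# ---------------------------------------------------------------------------
# post hocs and simple tests
# ---------------------------------------------------------------------------

def bonferroni_posthoc(table: pd.DataFrame, by: str = "location") -> pd.DataFrame:
    """Paired post-vs-pre comparisons within each level of ``by``.

    Raw paired-t p-values are multiplied by the number of comparisons and
    capped at 1 (Bonferroni).  Intended as the follow-up to a significant
    time x location interaction.
    """
    levels = list(dict.fromkeys(table[by]))
    m = len(levels)
    rows = []
    for lv in levels:
        sub = table[table[by] == lv].pivot_table(
            index="participant", columns="time", values="outcome")
        sub = sub.dropna()
        t, p = sps.ttest_rel(sub["post"], sub["pre"])
        rows.append({by: lv, "n": len(sub), "mean_diff": float((sub["post"] - sub["pre"]).mean()),
                     "t": float(t), "p_raw": float(p), "p_bonferroni": min(float(p) * m, 1.0)})
    return pd.DataFrame(rows)


def student_t_independent(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sided Student's t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("zero pooled variance: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def mann_whitney_u(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution for small samples (both n <= 12, no ties),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(paired_a: np.ndarray, paired_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need >= 2 pairs of equal length")
    diffs = a - b
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero: test undefined")
    n_nonzero = int(np.count_nonzero(diffs))
    ties = len(np.unique(np.abs(diffs[diffs != 0]))) < n_nonzero
    method = "exact" if (n_nonzero <= 25 and not ties) else "approx"
    res = sps.wilcoxon(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
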