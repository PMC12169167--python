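"""Test-retest reliability: ICC(3,1), typical error, coefficient of variation.

These are the statistics reported for inter-day reliability of tendon CSA,
stiffness and shear-wave velocity between a familiarisation and a baseline
session.  ICC(3,1) is the two-way mixed, consistency, single-measure
intraclass correlation (Shrout-Fleiss model 3); the typical error is
sd(between-session differences)/sqrt(2); the CV expresses the typical error
as a percentage of the grand mean (Hopkins' definitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _as_table(values: np.ndarray | pd.DataFrame, min_n: int = 2) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        values = values.to_numpy()
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("retest table must be participants x 2 sessions")
    if arr.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} participants")
    if not np.all(np.isfinite(arr)):
        raise ValueError("retest table must have no missing cells")
    return arr


def icc_3_1(values: np.ndarray | pd.DataFrame) -> tuple[float, bool]:
    """ICC(3,1) from the two-way subject x session mean squares.

    ``(MS_subjects - MS_error) / (MS_subjects + (k - 1) * MS_error)`` with
    k = 2 sessions.  Returns ``(icc, degenerate)`` where ``degenerate`` flags
    tables with (near-)zero between-subject variance, for which the estimate
    is <= 0 by construction.
    """
    arr = _as_table(values, min_n=3)
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:  # all values identical
        return 1.0, True
    icc = float((ms_rows - ms_err) / denom)
    return icc, icc <= 0


def typical_error(values: np.ndarray | pd.DataFrame) -> float:
    """sd of the between-session differences divided by sqrt(2)."""
    arr = _as_table(values)
    diffs = arr[:, 1] - arr[:, 0]
    return float(np.std(diffs, ddof=1) / np.sqrt(2.0))


def coefficient_of_variation(values: np.ndarray | pd.DataFrame) -> float:
    """100 * TE / grand mean, percent.  Requires a nonzero grand mean."""
    arr = _as_table(values)
    grand = arr.mean()
    if grand == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(100.0 * typical_error(arr) / grand)


@dataclass(frozen=True)
class ReliabilityRow:
    outcome: str
    n: int
    icc: float
    icc_degenerate: bool
    te: float
    cv_percent: float


def reliability_summary(values: np.ndarray | pd.DataFrame, outcome: str = "outcome") -> ReliabilityRow:
    """All three reliability statistics for one outcome's retest table."""
    arr = _as_table(values)
    icc, degen = icc_3_1(arr)
    return ReliabilityRow(
        outcome=outcome,
        n=arr.shape[0],
        icc=icc,
        icc_degenerate=degen,
        te=typical_error(arr),
        cv_percent=coefficient_of_variation(arr),
    )
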