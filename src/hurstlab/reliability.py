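"""Between-day ICC(3,k) reliability grids for Hurst-exponent estimates.

The design mirrors a test-retest gait protocol: each subject walks 9 trials
on each of 2 days; per-trial Hurst estimates are averaged over the first k
trials of each day (k = 1..9), and the agreement of the two day-averages
across subjects is summarized by the two-way mixed-effects consistency ICC
with days as the repeated measurements, ICC(3,k) = (BMS - EMS) / BMS. The
grid repeats this over stride counts, slicing the last n strides of every
trial (end-of-trial slices avoid familiarization effects at trial onset).

Qualitative bands: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent
(boundary values take the upper band).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .estimators import estimate_h_batch
from .types import ICCResult, StrideSeries, icc_band

__all__ = [
    "slice_last_strides",
    "day_average",
    "icc_3k",
    "reliability_grid",
]

GRID_COLUMNS = [
    "group", "variable", "method", "stride_count", "trials_used",
    "icc", "f_stat", "df1", "df2", "ci_low", "ci_high", "band",
]


def slice_last_strides(series: StrideSeries, n: int) -> StrideSeries:
    """The final n consecutive strides of a trial, labels retained."""
    n = int(n)
    if n < 1:
        raise ValueError("n must be positive")
    if len(series) < n:
        raise ValueError(f"series has {len(series)} strides, fewer than {n}")
    return replace(series, values=series.values[-n:])


def day_average(estimates: Sequence[float], k: int) -> float:
    """Mean of the first k per-trial estimates (trials in acquisition order)."""
    est = np.asarray(estimates, dtype=float)
    if k < 1:
        raise ValueError("k must be positive")
    if est.size < k:
        raise ValueError(f"only {est.size} trial estimates available, need {k}")
    return float(est[:k].mean())


def icc_3k(table, alpha: float = 0.05) -> ICCResult:
    """ICC(3,k): two-way mixed-effects, consistency, average of k measurements.

    ``table`` is subjects x measurements (here: 2 day-averages per subject).
    The 95% CI uses the Shrout-Fleiss F-bounds on BMS/EMS. Degenerate input
    with zero between-subject variance is signaled, not NaN-propagated.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ValueError("table must be 2-D (subjects x measurements)")
    n, k = y.shape
    if n < 3:
        raise ValueError("at least 3 subjects are required")
    if k < 2:
        raise ValueError("at least 2 repeated measurements are required")
    if not np.all(np.isfinite(y)):
        raise ValueError("table contains non-finite values")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)

    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    bms = ss_rows / df1
    ems = ss_err / df2
    if bms <= 0.0:
        raise ValueError("zero between-subject variance: ICC undefined")

    if ems == 0.0 or ss_err <= 1e-12 * ss_total:  # exact repeat up to rounding
        return ICCResult(icc=1.0, f_stat=np.inf, df1=df1, df2=df2,
                         ci_low=1.0, ci_high=1.0, band=icc_band(1.0))
    icc = (bms - ems) / bms
    f_obs = bms / ems
    f_low = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_high = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = 1.0 - 1.0 / f_low
    ci_high = 1.0 - 1.0 / f_high
    return ICCResult(
        icc=float(icc), f_stat=float(f_obs), df1=df1, df2=df2,
        ci_low=float(ci_low), ci_high=float(ci_high), band=icc_band(float(icc)),
    )


def _pivot_values(sub: pd.DataFrame, subjects, n_days: int, n_trials: int) -> np.ndarray:
    """Stack one (group, variable) slice into (subject, day, trial, stride)."""
    sub = sub.sort_values(["subject", "day", "trial", "stride"], kind="mergesort")
    counts = sub.groupby(["subject", "day", "trial"], sort=False)["value"].size()
    if counts.nunique() != 1:
        raise ValueError("unequal stride counts across trials; cannot form grid")
    n_strides = int(counts.iloc[0])
    arr = sub["value"].to_numpy().reshape(len(subjects), n_days, n_trials, n_strides)
    return arr


def reliability_grid(
    cohort: pd.DataFrame,
    method: str,
    stride_counts: Iterable[int],
    trials_used: Iterable[int] = range(1, 10),
    group: Optional[str] = None,
    variable: Optional[str] = None,
    truth: Optional[pd.DataFrame] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Between-day ICC(3,k) over stride-count x trials-used, per group/variable.

    For each stride count the last n strides of every trial are estimated
    once (shared across all k); for each k the first k trials of each day
    are averaged and ICC(3,k) computed across subjects. ``method`` is "dfa",
    "hkp", or "true" (bypass estimation, read the companion ``truth`` table —
    the oracle path for validating the pipeline itself). Cells that cannot
    be computed are flagged with band="failed", never dropped.
    """
    method = method.lower()
    if method == "true" and truth is None:
        raise ValueError('method="true" requires the truth table')
    stride_counts = list(stride_counts)
    trials_used = list(trials_used)

    df = cohort
    if group is not None:
        df = df[df["group"] == group]
    if variable is not None:
        df = df[df["variable"] == variable]
    if df.empty:
        raise ValueError("no cohort rows match the requested group/variable")

    rows = []
    combos = df.groupby(["group", "variable"], sort=True)
    for ci, ((grp, var), sub) in enumerate(combos):
        subjects = np.sort(sub["subject"].unique())
        days = np.sort(sub["day"].unique())
        trials = np.sort(sub["trial"].unique())
        n_days, n_trials = days.size, trials.size
        if n_days != 2:
            raise ValueError("between-day reliability requires exactly 2 days")
        if n_trials < max(trials_used):
            raise ValueError("cohort has fewer trials than requested")
        arr = _pivot_values(sub, subjects, n_days, n_trials)

        if method == "true":
            tsub = truth[(truth["group"] == grp)].sort_values(
                ["subject", "day", "trial"], kind="mergesort")
            est_cube = tsub["true_h"].to_numpy().reshape(
                len(subjects), n_days, n_trials)
            est_by_stride = {s: est_cube for s in stride_counts}
        else:
            est_by_stride = {}
            for si, s in enumerate(stride_counts):
                if s > arr.shape[3]:
                    raise ValueError(f"stride count {s} exceeds trial length {arr.shape[3]}")
                flat = arr[:, :, :, -s:].reshape(-1, s)
                est = estimate_h_batch(flat, method, rng=child_rng(seed, ci, si))
                est_by_stride[s] = est.reshape(len(subjects), n_days, n_trials)

        for s in stride_counts:
            est_cube = est_by_stride[s]
            for k in trials_used:
                try:
                    day_avg = est_cube[:, :, :k].mean(axis=2)
                    res = icc_3k(day_avg)
                    rows.append([grp, var, method, s, k, res.icc, res.f_stat,
                                 res.df1, res.df2, res.ci_low, res.ci_high, res.band])
                except (ValueError, FloatingPointError):
                    rows.append([grp, var, method, s, k, np.nan, np.nan,
                                 np.nan, np.nan, np.nan, np.nan, "failed"])
    return pd.DataFrame(rows, columns=GRID_COLUMNS)
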