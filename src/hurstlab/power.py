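"""Monte-Carlo statistical power and minimum-sample-size search.

Simulates a two-group cross-sectional design: group A subjects have mean
true Hurst exponent 0.75, group B mean 0.75 + delta_h; per-subject trial-
level true H values share a between-trial ICC of 0.65 (compound symmetry,
marginal SD 0.11), each trial is an independent fGn realization at its true
H, the Hurst exponent is estimated per trial (DFA or HKp) and averaged
within subject, and the group means are compared with a two-sided Welch
t-test at alpha = 0.05. Power is the rejection proportion over replicates.

The minimum-n search shares subject draws across the n grid (common random
numbers): each replicate simulates the largest n once and every smaller n
reuses its first subjects, which suppresses Monte-Carlo jitter between
adjacent grid points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .estimators import estimate_h_batch
from .fgn import sample_correlated_trial_h, simulate_fgn_batch

__all__ = [
    "PowerCondition",
    "PowerResult",
    "MinNResult",
    "simulate_replicate",
    "estimate_power",
    "power_curve",
    "min_n_for_power",
    "power_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerCondition:
    """One simulation condition of the two-group design."""

    delta_h: float
    n_per_group: int = 30
    n_trials: int = 1
    series_length: int = 100
    method: str = "hkp"  # "dfa" | "hkp" | "true" (bypass estimation)
    mean_a: float = 0.75
    within_sd: float = 0.11
    trial_icc: float = 0.65
    alpha: float = 0.05
    welch: bool = True
    truncate: str = "clip"  # support handling for sampled true H; see fgn module

    def validate(self) -> None:
        if self.delta_h < 0:
            raise ValueError("delta_h must be nonnegative")
        if not (0.0 < self.mean_a < 1.0) or not (0.0 < self.mean_a + self.delta_h < 1.0):
            raise ValueError("group means must lie in (0, 1)")
        if self.n_per_group < 2 or self.n_trials < 1:
            raise ValueError("n_per_group >= 2 and n_trials >= 1 required")
        if self.series_length < 16:
            raise ValueError("series_length must be at least 16")
        if self.method not in ("dfa", "hkp", "true"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class PowerResult:
    condition: PowerCondition
    reps: int
    rejections: int
    power: float
    ci_low: float
    ci_high: float
    seed: int
    n_failed_estimates: int = 0


@dataclass
class MinNResult:
    """Smallest n per group on the grid reaching the target power."""

    min_n: Optional[int]
    target: float
    n_grid: Sequence[int]
    powers: pd.DataFrame = field(repr=False)

    @property
    def attained(self) -> bool:
        return self.min_n is not None

    def __str__(self) -> str:
        return str(self.min_n) if self.attained else f"> {max(self.n_grid)}"


def _binom_ci(k: int, n: int, level: float = 0.95):
    """Clopper-Pearson interval for a binomial proportion."""
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def _welch_pvalues(a: np.ndarray, b: np.ndarray, welch: bool = True) -> np.ndarray:
    """Two-sided two-sample t-test p-values along axis 1."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    return np.atleast_1d(res.pvalue)


def _replicate_data(cond: PowerCondition, n_max: int, rng):
    """True-H matrices and stacked fGn series for one replicate.

    Returns (true_h, series) with true_h shape (2, n_max, n_trials) and
    series shape (2 * n_max * n_trials, series_length); series is None in
    bypass mode.
    """
    t = cond.n_trials
    h_a = sample_correlated_trial_h(
        cond.mean_a, cond.within_sd, cond.trial_icc, t, n_max,
        rng=rng, truncate=cond.truncate,
    ).values
    h_b = sample_correlated_trial_h(
        cond.mean_a + cond.delta_h, cond.within_sd, cond.trial_icc, t, n_max,
        rng=rng, truncate=cond.truncate,
    ).values
    true_h = np.stack([h_a, h_b])
    if cond.method == "true":
        return true_h, None
    series = simulate_fgn_batch(true_h.reshape(-1), cond.series_length, rng=rng)
    return true_h, series


def _subject_means(
    cond: PowerCondition,
    n_max: int,
    reps: int,
    seed: int,
    chunk_reps: Optional[int] = None,
) -> tuple[np.ndarray, int]:
    """Per-subject across-trial mean H estimates; shape (reps, 2, n_max).

    Data generation is per-replicate (own seed stream); the expensive
    estimation step is batched across a chunk of replicates. Replicates with
    a failed (non-finite) estimate are regenerated under the next attempt
    sub-seed; the count of such events is returned.
    """
    t = cond.n_trials
    per_rep = 2 * n_max * t
    if chunk_reps is None:
        # target roughly 2000 series per estimation sweep
        chunk_reps = max(1, int(np.ceil(2000 / per_rep)))
    means = np.empty((reps, 2, n_max))
    n_failed = 0
    for start in range(0, reps, chunk_reps):
        reps_idx = range(start, min(start + chunk_reps, reps))
        blocks = []
        truths = []
        for rep in reps_idx:
            true_h, series = _replicate_data(cond, n_max, child_rng(seed, 0, rep))
            truths.append(true_h)
            if series is not None:
                blocks.append(series)
        if cond.method == "true":
            est = np.stack(truths)  # (chunk, 2, n_max, t)
        else:
            stacked = np.concatenate(blocks, axis=0)
            est = estimate_h_batch(
                stacked, cond.method, rng=child_rng(seed, 1, start)
            ).reshape(len(blocks), 2, n_max, t)
            bad = ~np.isfinite(est).all(axis=(1, 2, 3))
            for j in np.nonzero(bad)[0]:
                rep = start + j
                est[j] = _retry_replicate(cond, n_max, seed, rep)
                n_failed += 1
        means[list(reps_idx)] = est.mean(axis=3)
    return means, n_failed


def _retry_replicate(cond: PowerCondition, n_max: int, seed: int, rep: int) -> np.ndarray:
    for attempt in range(1, 20):
        logger.warning("replicate %d: failed estimate, redrawing (attempt %d)", rep, attempt)
        true_h, series = _replicate_data(cond, n_max, child_rng(seed, 0, rep, attempt))
        est = estimate_h_batch(series, cond.method, rng=child_rng(seed, 2, rep, attempt))
        est = est.reshape(2, n_max, cond.n_trials)
        if np.isfinite(est).all():
            return est
    raise RuntimeError(f"replicate {rep}: estimation kept failing after redraws")


def simulate_replicate(cond: PowerCondition, replicate_seed: int) -> bool:
    """One replicate of the design; True when the null is rejected."""
    cond.validate()
    means, _ = _subject_means(cond, cond.n_per_group, 1, replicate_seed)
    p = _welch_pvalues(means[:, 0, :], means[:, 1, :], cond.welch)[0]
    return bool(p < cond.alpha)


def power_curve(
    cond: PowerCondition,
    n_grid: Iterable[int],
    reps: int,
    seed: int,
) -> pd.DataFrame:
    """Estimated power at each n of the grid, with common random numbers.

    Returns a tidy frame (n, reps, rejections, power, ci_low, ci_high).
    """
    cond.validate()
    n_grid = sorted(int(n) for n in n_grid)
    if reps < 1:
        raise ValueError("reps must be positive")
    n_max = max(n_grid)
    means, n_failed = _subject_means(cond, n_max, reps, seed)
    if n_failed:
        logger.info("%d replicates regenerated after estimation failures", n_failed)
    rows = []
    for n in n_grid:
        p = _welch_pvalues(means[:, 0, :n], means[:, 1, :n], cond.welch)
        rej = int((p < cond.alpha).sum())
        lo, hi = _binom_ci(rej, reps)
        rows.append([n, reps, rej, rej / reps, lo, hi])
    return pd.DataFrame(
        rows, columns=["n", "reps", "rejections", "power", "ci_low", "ci_high"]
    )


def estimate_power(cond: PowerCondition, reps: int, seed: int) -> PowerResult:
    """Power at the condition's own n_per_group over ``reps`` replicates."""
    curve = power_curve(cond, [cond.n_per_group], reps, seed)
    row = curve.iloc[0]
    return PowerResult(
        condition=cond, reps=reps, rejections=int(row["rejections"]),
        power=float(row["power"]), ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]), seed=seed,
    )


def min_n_for_power(
    cond: PowerCondition,
    n_grid: Iterable[int],
    reps: int,
    seed: int,
    target: float = 0.8,
) -> MinNResult:
    """Smallest grid n whose estimated power reaches ``target``.

    Returns a sentinel (min_n=None, printed "> max") when the target is not
    attained anywhere on the grid.
    """
    curve = power_curve(cond, n_grid, reps, seed)
    hit = curve[curve["power"] >= target]
    min_n = int(hit["n"].iloc[0]) if not hit.empty else None
    return MinNResult(min_n=min_n, target=target,
                      n_grid=curve["n"].tolist(), powers=curve)


def power_table(
    conditions: Sequence[PowerCondition],
    reps: int,
    seed: int,
    path=None,
) -> pd.DataFrame:
    """Batch power estimation over many conditions; one tidy row each."""
    rows = []
    for i, cond in enumerate(conditions):
        cond_seed = int(child_rng(seed, 10, i).integers(0, 2**31 - 1))
        res = estimate_power(cond, reps, cond_seed)
        rows.append({
            "delta_h": cond.delta_h, "n_per_group": cond.n_per_group,
            "n_trials": cond.n_trials, "series_length": cond.series_length,
            "method": cond.method, "alpha": cond.alpha, "reps": reps,
            "seed": cond_seed, "rejections": res.rejections,
            "power": res.power, "ci_low": res.ci_low, "ci_high": res.ci_high,
        })
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return table
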