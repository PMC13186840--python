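"""Detrended Fluctuation Analysis (DFA) for short stationary series.

The series is mean-centered and integrated; the profile is split into
non-overlapping windows of size n (anchored at the start, trailing remainder
discarded), a first-degree OLS trend is removed within each window, and the
fluctuation function F(n) is the root mean squared residual over all retained
points. The scaling exponent alpha is the unweighted OLS slope of log F(n)
on log n over every integer scale in [4, N/4] — a range wide enough to be
usable on very short stride series. For stationary signals alpha estimates
the Hurst exponent (alpha = 0.5 for uncorrelated noise).
"""

from __future__ import annotations

import numpy as np

from .types import DFAFit, HurstEstimate, as_values

__all__ = [
    "integrate_series",
    "fluctuation_at_scale",
    "dfa_scales",
    "dfa_estimate",
    "dfa_alpha_batch",
]

MIN_SCALE = 4


def integrate_series(series) -> np.ndarray:
    """Cumulative sum of the mean-centered values (the DFA profile)."""
    x = as_values(series)
    if x.size < 8:
        raise ValueError("series must have at least 8 points")
    return np.cumsum(x - x.mean())


def dfa_scales(n_points: int) -> np.ndarray:
    """All integer window sizes in [4, floor(N/4)]."""
    return np.arange(MIN_SCALE, n_points // 4 + 1)


def fluctuation_at_scale(profile, n: int) -> float:
    """Root mean squared residual of per-window linear detrending at scale n."""
    profile = np.asarray(profile, dtype=float)
    total = profile.size
    n = int(n)
    if not (MIN_SCALE <= n <= total // 4):
        raise ValueError(f"scale {n} outside [4, {total // 4}] for N={total}")
    return float(_fluctuations(profile[None, :], np.array([n]))[0, 0])


def _fluctuations(profiles: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """F(n) for each profile row and scale; shape (m, len(scales))."""
    m, total = profiles.shape
    out = np.empty((m, scales.size))
    for j, w in enumerate(scales):
        k = total // w
        seg = profiles[:, : k * w].reshape(m, k, w)
        t = np.arange(w, dtype=float)
        tc = t - t.mean()
        denom = (tc * tc).sum()
        slope = (seg * tc).sum(axis=2) / denom
        resid = seg - seg.mean(axis=2, keepdims=True) - slope[:, :, None] * tc
        out[:, j] = np.sqrt((resid * resid).mean(axis=(1, 2)))
    return out


def dfa_alpha_batch(series_matrix: np.ndarray) -> np.ndarray:
    """DFA alpha for each row of an (m, N) matrix of equal-length series.

    Rows for which fewer than 3 scales have positive fluctuation yield NaN.
    """
    x = np.atleast_2d(np.asarray(series_matrix, dtype=float))
    m, total = x.shape
    if total < 16:
        raise ValueError("series must have at least 16 points for DFA")
    profiles = np.cumsum(x - x.mean(axis=1, keepdims=True), axis=1)
    scales = dfa_scales(total)
    fl = _fluctuations(profiles, scales)
    log_n = np.log(scales)
    alphas = np.empty(m)
    for i in range(m):
        ok = fl[i] > 0.0
        if ok.sum() < 3:
            alphas[i] = np.nan
            continue
        if ok.all():
            alphas[i] = np.polyfit(log_n, np.log(fl[i]), 1)[0]
        else:
            alphas[i] = np.polyfit(log_n[ok], np.log(fl[i, ok]), 1)[0]
    return alphas


def dfa_estimate(series) -> HurstEstimate:
    """Full DFA fit for one series, with per-scale diagnostics retained."""
    x = as_values(series)
    if x.size < 16:
        raise ValueError("series must have at least 16 points for DFA")
    profile = np.cumsum(x - x.mean())
    scales = dfa_scales(x.size)
    fl = _fluctuations(profile[None, :], scales)[0]
    ok = fl > 0.0
    if ok.sum() < 3:
        raise ValueError("fewer than 3 scales with positive fluctuation")
    log_n = np.log(scales[ok])
    log_f = np.log(fl[ok])
    slope, intercept = np.polyfit(log_n, log_f, 1)
    fitted = intercept + slope * log_n
    ss_res = float(((log_f - fitted) ** 2).sum())
    ss_tot = float(((log_f - log_f.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    fit = DFAFit(
        scales=scales,
        fluctuations=fl,
        alpha=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        excluded_scales=scales[~ok],
    )
    return HurstEstimate(method="dfa", point=float(slope), diagnostics=fit)
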