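"""Exact fractional Gaussian noise simulation and synthetic gait cohorts.

Fractional Gaussian noise (fGn) is the stationary Gaussian process whose
autocorrelation at lag k is

    rho_k = 1/2 |k+1|^(2H) + 1/2 |k-1|^(2H) - |k|^(2H)

with Hurst exponent H in (0, 1): H = 0.5 is white noise, H > 0.5 gives
persistent (long-range correlated) series such as healthy stride-interval
dynamics, H < 0.5 anti-persistent ones.

Simulation uses circulant embedding (Davies-Harte), which reproduces the
target autocovariance exactly, with a Cholesky-of-Toeplitz fallback should
the embedding ever fail to be nonnegative definite. Series are generated
with mean 0; the estimators are affine-invariant so the scale is a free
choice and defaults to sd 1.

The module also draws correlated trial-level "true" Hurst exponents
(compound-symmetry multivariate normal realized through its Cholesky
factor) and assembles long-format synthetic cohorts that mirror a
two-day, nine-trials-per-day overground walking protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from ._rng import as_rng, child_rng
from .types import CorrelationVector, StrideSeries, TrialHMatrix

__all__ = [
    "hk_autocorrelation",
    "simulate_fgn",
    "simulate_fgn_batch",
    "sample_correlated_trial_h",
    "CohortConfig",
    "generate_cohort",
    "write_cohort",
    "day_sd_for_target_icc",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject", "group", "day", "trial", "variable", "stride", "value"]
TRUTH_COLUMNS = ["subject", "group", "day", "trial", "true_h"]

# Plausible marginal mean/SD used to place simulated series on each gait
# variable's native scale (s, m, deg). Affine placement only; H is unaffected.
VARIABLE_PROFILES: Mapping[str, Tuple[float, float]] = {
    "stride_interval": (1.10, 0.035),
    "stride_length": (1.40, 0.046),
    "hip_rom": (42.0, 1.8),
    "knee_rom": (62.0, 2.2),
    "ankle_rom": (28.0, 1.5),
}


def _check_hurst_open(h: float) -> None:
    if not (0.0 < h < 1.0):
        raise ValueError(f"hurst must lie in (0, 1), got {h}")


def hk_autocorrelation(hurst: float, max_lag: int) -> CorrelationVector:
    """Theoretical Hurst-Kolmogorov autocorrelation rho_0..rho_max_lag.

    Valid for hurst in (0, 1]; rho_0 evaluates to 1 from the formula itself.
    """
    if not (0.0 < hurst <= 1.0):
        raise ValueError(f"hurst must lie in (0, 1], got {hurst}")
    if max_lag < 0:
        raise ValueError("max_lag must be nonnegative")
    rho = _hk_rho_rows(np.array([hurst]), max_lag)[0]
    return CorrelationVector(hurst=float(hurst), max_lag=int(max_lag), rho=rho)


def _hk_rho_rows(hursts: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation rows, shape (len(hursts), max_lag + 1)."""
    k = np.arange(max_lag + 1, dtype=float)[None, :]
    two_h = 2.0 * np.asarray(hursts, dtype=float)[:, None]
    return (
        0.5 * np.abs(k + 1.0) ** two_h
        + 0.5 * np.abs(k - 1.0) ** two_h
        - k ** two_h
    )


def simulate_fgn_batch(
    hursts: Sequence[float],
    length: int,
    sd: float = 1.0,
    rng=None,
) -> np.ndarray:
    """Simulate one fGn series per entry of ``hursts``; shape (m, length).

    Circulant embedding of the autocovariance is exact: each output row is a
    zero-mean Gaussian vector whose covariance is sd^2 * Toeplitz(rho(H_i)).
    Rows whose embedding has a negative eigenvalue (not expected for fGn)
    fall back to Cholesky of the dense Toeplitz covariance.
    """
    hursts = np.asarray(hursts, dtype=float)
    if hursts.ndim != 1:
        raise ValueError("hursts must be 1-D")
    if np.any(hursts <= 0.0) or np.any(hursts >= 1.0):
        raise ValueError("all hurst values must lie in (0, 1)")
    n = int(length)
    if n < 8:
        raise ValueError("length must be at least 8")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = as_rng(rng)
    m = hursts.size
    big = 2 * n

    rho = _hk_rho_rows(hursts, n)  # lags 0..n
    # circulant first row: rho_0..rho_n, rho_{n-1}..rho_1
    circ = np.concatenate([rho, rho[:, -2:0:-1]], axis=1)
    lam = np.fft.fft(circ, axis=1).real
    tol = -1e-8 * np.abs(lam).max(axis=1)
    bad = lam.min(axis=1) < tol
    lam = np.clip(lam, 0.0, None)

    # Hermitian-symmetric spectral draws -> real Gaussian output.
    z_re = rng.standard_normal((m, n + 1))
    z_im = rng.standard_normal((m, n - 1))
    w = np.zeros((m, big), dtype=complex)
    w[:, 0] = np.sqrt(lam[:, 0]) * z_re[:, 0]
    w[:, n] = np.sqrt(lam[:, n]) * z_re[:, n]
    half = np.sqrt(lam[:, 1:n] / 2.0)
    w[:, 1:n] = half * (z_re[:, 1:n] + 1j * z_im)
    w[:, n + 1:] = np.conj(w[:, 1:n][:, ::-1])
    x = np.fft.fft(w, axis=1)[:, :n].real / np.sqrt(big)

    if np.any(bad):
        logger.warning("circulant embedding not PSD for %d series; Cholesky fallback", bad.sum())
        for i in np.nonzero(bad)[0]:
            x[i] = _fgn_cholesky(rho[i, :n], rng)
    return sd * x


def _fgn_cholesky(rho_row: np.ndarray, rng) -> np.ndarray:
    cov = toeplitz(rho_row)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    return chol @ rng.standard_normal(cov.shape[0])


def simulate_fgn(
    hurst: float,
    length: int,
    sd: float = 1.0,
    seed=None,
    **labels,
) -> StrideSeries:
    """Simulate a single fGn series as a StrideSeries (reproducible by seed)."""
    _check_hurst_open(hurst)
    rng = as_rng(seed)
    x = simulate_fgn_batch(np.array([hurst]), length, sd=sd, rng=rng)[0]
    return StrideSeries(values=x, **labels)


def sample_correlated_trial_h(
    mean: float,
    sd: float,
    icc: float,
    n_trials: int,
    n_subjects: int,
    rng=None,
    seed=None,
    truncate: str = "clip",
    max_iter: int = 10_000,
    clip_eps: float = 0.001,
) -> TrialHMatrix:
    """Draw per-subject trial-level true Hurst exponents.

    Each row is multivariate normal with marginal mean ``mean``, marginal sd
    ``sd`` and compound-symmetry correlation ``icc`` between every pair of
    trials, realized via the Cholesky factor of that covariance. Values must
    end up inside the open unit interval (the fGn support); ``truncate``
    selects how out-of-range draws are handled:

    - ``"clip"`` (default): clamp to [clip_eps, 1 - clip_eps]. Distorts the
      marginal mean least (the shift is E[X - min(X, 1)] ~ 0.003 for mean
      0.83, sd 0.11), so the realized between-group difference stays at its
      nominal value — the property the power study depends on.
    - ``"resample"``: redraw whole rows containing an out-of-range value.
      Preserves normality inside the support but shifts the mean toward 0.5
      (~0.014 at mean 0.83), attenuating between-group differences.
    - ``"none"``: raise if any draw falls outside (0, 1).

    ``n_resampled`` on the result counts affected rows under either scheme.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not (0.0 <= icc <= 1.0):
        raise ValueError("icc must lie in [0, 1]")
    if n_trials < 1 or n_subjects < 1:
        raise ValueError("n_trials and n_subjects must be positive")
    rng = as_rng(rng if rng is not None else seed)

    if icc == 1.0:
        # Rank-1 covariance: one shared draw per subject.
        chol = None
    else:
        cov = sd * sd * ((1.0 - icc) * np.eye(n_trials) + icc * np.ones((n_trials, n_trials)))
        chol = np.linalg.cholesky(cov)

    def draw(k: int) -> np.ndarray:
        if chol is None:
            return mean + sd * np.repeat(rng.standard_normal((k, 1)), n_trials, axis=1)
        return mean + rng.standard_normal((k, n_trials)) @ chol.T

    values = draw(n_subjects)
    n_resampled = 0
    if truncate == "clip":
        bad = (values <= 0.0) | (values >= 1.0)
        n_resampled = int(np.any(bad, axis=1).sum())
        values = np.clip(values, clip_eps, 1.0 - clip_eps)
    elif truncate == "resample":
        for _ in range(max_iter):
            bad = np.any((values <= 0.0) | (values >= 1.0), axis=1)
            if not bad.any():
                break
            n_resampled += int(bad.sum())
            values[bad] = draw(int(bad.sum()))
        else:
            raise RuntimeError("rejection resampling failed to converge")
    elif truncate == "none":
        if np.any((values <= 0.0) | (values >= 1.0)):
            raise ValueError("sampled true H outside (0, 1) with truncate='none'")
    else:
        raise ValueError(f"unknown truncate mode {truncate!r}")
    return TrialHMatrix(
        values=values,
        target_mean=float(mean),
        target_sd=float(sd),
        target_icc=float(icc),
        n_resampled=n_resampled,
    )


def day_sd_for_target_icc(
    target_icc: float,
    sd_subject: float,
    sd_trial: float,
    n_trials: int,
    n_days: int = 2,
) -> float:
    """Between-day true-H sd giving a designed day-average ICC(3, n_days).

    For day averages of ``n_trials`` trials, the population average-measures
    consistency ICC is sigma_s^2 / (sigma_s^2 + sigma_v^2 / n_days) with
    sigma_v^2 = sd_day^2 + sd_trial^2 / n_trials; solve for sd_day.
    """
    if not (0.0 < target_icc < 1.0):
        raise ValueError("target_icc must lie strictly in (0, 1)")
    var_within = n_days * sd_subject**2 * (1.0 / target_icc - 1.0)
    var_day = var_within - sd_trial**2 / n_trials
    if var_day < 0:
        raise ValueError(
            "sd_trial too large for the requested ICC; reduce sd_trial or n_trials"
        )
    return float(np.sqrt(var_day))


@dataclass
class CohortConfig:
    """Design of a synthetic multi-group gait cohort.

    True Hurst exponents follow a variance-components model
    H = group mean + subject + (subject x day) + (subject x day x trial),
    with each effect an independent zero-mean normal of the configured sd.
    A subject whose 2 x 9 true-H block leaves (0, 1) is redrawn whole.
    Every trial is an independent fGn realization at that cell's true H;
    each variable gets its own realization (same true H) and is placed on
    its native scale by an affine map.
    """

    groups: Mapping[str, float] = field(
        default_factory=lambda: {"young": 0.75, "middle_aged": 0.75, "older": 0.75}
    )
    n_subjects: int = 20
    n_days: int = 2
    n_trials: int = 9
    n_strides: int = 200
    variables: Sequence[str] = ("stride_interval",)
    sd_subject: float = 0.11
    sd_day: float = 0.03
    sd_trial: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for g, mu in self.groups.items():
            if not (0.0 < mu < 1.0):
                raise ValueError(f"group {g!r} mean H must lie in (0, 1)")
        if self.n_subjects < 1 or self.n_days < 1 or self.n_trials < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.n_strides < 8:
            raise ValueError("n_strides must be at least 8")
        if min(self.sd_subject, self.sd_day, self.sd_trial) < 0:
            raise ValueError("variance components must be nonnegative")


def generate_cohort(config: CohortConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format synthetic cohort and its true-H companion table.

    Returns ``(cohort, truth)``: the cohort has columns
    subject,group,day,trial,variable,stride,value and the truth table has
    subject,group,day,trial,true_h.
    """
    config.validate()
    cohort_parts = []
    truth_parts = []
    cells_per_subj = config.n_days * config.n_trials

    for gi, (group, mu) in enumerate(config.groups.items()):
        rng_h = child_rng(config.seed, 0, gi)
        true_h = np.empty((config.n_subjects, config.n_days, config.n_trials))
        for i in range(config.n_subjects):
            for _ in range(10_000):
                s = rng_h.normal(0.0, config.sd_subject)
                d = rng_h.normal(0.0, config.sd_day, size=config.n_days)
                e = rng_h.normal(0.0, config.sd_trial, size=(config.n_days, config.n_trials))
                h = mu + s + d[:, None] + e
                if np.all((h > 0.0) & (h < 1.0)):
                    true_h[i] = h
                    break
            else:
                raise RuntimeError("could not draw an in-range true-H block")

        subjects = [f"{group}_{i + 1:03d}" for i in range(config.n_subjects)]
        days = np.arange(1, config.n_days + 1)
        trials = np.arange(1, config.n_trials + 1)
        idx = pd.MultiIndex.from_product(
            [subjects, days, trials], names=["subject", "day", "trial"]
        )
        truth = pd.DataFrame(idx.to_frame(index=False))
        truth.insert(1, "group", group)
        truth["true_h"] = true_h.reshape(-1)
        truth_parts.append(truth)

        flat_h = true_h.reshape(-1)
        for vi, variable in enumerate(config.variables):
            rng_x = child_rng(config.seed, 1, gi, vi)
            x = simulate_fgn_batch(flat_h, config.n_strides, rng=rng_x)
            loc, scale = VARIABLE_PROFILES.get(variable, (0.0, 1.0))
            x = loc + scale * x
            part = truth.loc[truth.index.repeat(config.n_strides),
                             ["subject", "group", "day", "trial"]].reset_index(drop=True)
            part["variable"] = variable
            part["stride"] = np.tile(
                np.arange(1, config.n_strides + 1), config.n_subjects * cells_per_subj
            )
            part["value"] = x.reshape(-1)
            cohort_parts.append(part)

    cohort = pd.concat(cohort_parts, ignore_index=True)[COHORT_COLUMNS]
    truth = pd.concat(truth_parts, ignore_index=True)[TRUTH_COLUMNS]
    return cohort, truth


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort (or truth) table; byte-identical across reruns."""
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
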