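"""Core value objects shared across the estimation and analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "StrideSeries",
    "CorrelationVector",
    "TrialHMatrix",
    "DFAFit",
    "HKPosterior",
    "HurstEstimate",
    "ICCResult",
    "as_values",
]


@dataclass
class StrideSeries:
    """One trial's ordered stride-level values with its identifying labels.

    Values are in the variable's native units (seconds for stride interval,
    meters for stride length, degrees for joint range of motion,
    dimensionless for simulated fractional Gaussian noise). Both estimators
    are affine-invariant, so units never affect the Hurst exponent.
    """

    values: np.ndarray
    subject: str = "sim"
    group: str = "sim"
    day: int = 1
    trial: int = 1
    variable: str = "simulated_fgn"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("StrideSeries values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("StrideSeries values must all be finite")

    def __len__(self) -> int:
        return self.values.size


def as_values(series) -> np.ndarray:
    """Extract the float array from a StrideSeries or array-like."""
    if isinstance(series, StrideSeries):
        return series.values
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    return x


@dataclass
class CorrelationVector:
    """Theoretical Hurst-Kolmogorov autocorrelations rho_0..rho_K for one H."""

    hurst: float
    max_lag: int
    rho: np.ndarray


@dataclass
class TrialHMatrix:
    """True Hurst exponents, one row per subject, one column per trial.

    Rows are draws from a compound-symmetry multivariate normal (common
    pairwise correlation = the design's between-trial ICC); rows containing
    a value outside (0, 1) are rejected and redrawn, and ``n_resampled``
    records how many redraws were needed so the moment distortion can be
    reported.
    """

    values: np.ndarray
    target_mean: float
    target_sd: float
    target_icc: float
    n_resampled: int = 0


@dataclass
class DFAFit:
    """Per-scale fluctuation function and the log-log regression behind alpha."""

    scales: np.ndarray
    fluctuations: np.ndarray
    alpha: float
    intercept: float
    r_squared: float
    excluded_scales: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class HKPosterior:
    """Peak of the (unnormalized) marginal posterior density of H."""

    peak_h: float
    peak_log_density: float

    @property
    def peak_density(self) -> float:
        """Density at the peak on the normalized-to-peak scale (always 1)."""
        return 1.0


@dataclass
class HurstEstimate:
    """Point estimate of the Hurst exponent with method-specific diagnostics."""

    method: str  # "dfa" | "hkp"
    point: float
    samples: Optional[np.ndarray] = None  # the 50 accepted H values (HKp only)
    diagnostics: Union[DFAFit, HKPosterior, None] = None


@dataclass
class ICCResult:
    """ICC(3,k) with its F test and Shrout-Fleiss 95% confidence interval."""

    icc: float
    f_stat: float
    df1: int
    df2: int
    ci_low: float
    ci_high: float
    band: str


def icc_band(icc: float) -> str:
    """Qualitative reliability band; boundary values take the upper band."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"
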