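"""Dispatch a batch of equal-length series to a Hurst estimator."""

from __future__ import annotations

import numpy as np

from .dfa import dfa_alpha_batch
from .hkp import hkp_estimate_batch

__all__ = ["estimate_h_batch", "METHODS"]

METHODS = ("dfa", "hkp")


def estimate_h_batch(series_matrix: np.ndarray, method: str, rng=None) -> np.ndarray:
    """Point estimates of H for each row of an (m, N) matrix.

    ``method`` is "dfa" (deterministic) or "hkp" (grid-accelerated
    accept-reject; ``rng`` seeds the candidate draws).
    """
    method = method.lower()
    if method == "dfa":
        return dfa_alpha_batch(series_matrix)
    if method == "hkp":
        return hkp_estimate_batch(series_matrix, rng=rng)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
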