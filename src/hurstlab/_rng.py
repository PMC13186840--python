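"""Seed-stream plumbing.

A single master seed is expanded into independent child streams through
``numpy.random.SeedSequence`` spawn keys, so every (condition, replicate,
attempt) gets its own reproducible generator regardless of execution order
or chunking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "as_rng"]


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for the child stream identified by ``key`` under ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce a seed, Generator, or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
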