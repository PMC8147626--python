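"""Deterministic seed splitting.

All randomness in the package flows from one user-facing integer seed per
operation. Sub-streams (obstacle placement, diffusion increments, localization
noise, camera noise, ...) are derived with ``numpy.random.SeedSequence`` spawn
keys, so every stage is bit-reproducible and statistically independent of its
siblings regardless of how much randomness the other stages consume.
"""

from __future__ import annotations

import numpy as np

__all__ = ["split_rng"]


def split_rng(seed: int | None, *keys: int) -> np.random.Generator:
    """Return a PCG64 generator for sub-stream ``keys`` of ``seed``.

    The same ``(seed, keys)`` pair always yields the same stream; different
    key tuples yield independent streams.
    """
    if seed is None:
        return np.random.default_rng()
    if int(seed) < 0:
        raise ValueError("seed must be a non-negative integer")
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in keys))
    return np.random.Generator(np.random.PCG64(ss))
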