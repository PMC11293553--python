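"""Deterministic seed derivation.

All randomness in the pipeline flows from one top-level integer seed.
Per-stage (and per-sample) generators are derived by hashing the stage
name onto the root seed, so stages are independent and insensitive to
the order in which they run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(seed: int, *tokens: str | int) -> int:
    """Derive a child seed < 2**31 from a root seed and string/int tokens."""
    h = zlib.crc32(str(int(seed)).encode())
    for tok in tokens:
        h = zlib.crc32(str(tok).encode(), h)
    return int(h % (2**31))


def substream(seed: int, *tokens: str | int) -> np.random.Generator:
    """A ``numpy.random.Generator`` keyed by (seed, tokens)."""
    return np.random.default_rng(subseed(seed, *tokens))
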