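"""Deterministic random-stream management.

Every stochastic component draws from a :class:`numpy.random.Generator` derived
from a root seed plus a tuple of string/int keys, so independent stages of a
study get independent streams and the whole run is a pure function of the root
seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"rng key must be int or str, got {type(key)!r}")


def child_seed(seed: int, *keys) -> int:
    """A 31-bit seed derived deterministically from ``seed`` and ``keys``."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Generator for the stream identified by ``(seed, *keys)``."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys])
    return np.random.Generator(np.random.PCG64(ss))
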