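"""Deterministic seed substreams.

One master seed per run; every stochastic step (SIR draws at a grid point,
copula draws for a subject, a bootstrap replicate, ...) pulls its own
named substream, so results never depend on iteration order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_ints(keys) -> list[int]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(k).encode("utf-8")))
    return out


def child_seed(seed: int, *keys) -> int:
    """A 31-bit integer seed derived deterministically from (seed, keys)."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + _key_ints(keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, *keys) -> np.random.Generator:
    """Generator on the substream named by ``keys`` under the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + _key_ints(keys))
    )
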