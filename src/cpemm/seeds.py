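"""Deterministic seed derivation.

Every stochastic component draws its seed from a single global seed plus
a string/int tag path, so one seed reproduces an entire run bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed"]


def child_seed(seed: int, *tags: int | str) -> int:
    """Derive a child seed (< 2**31) from a parent seed and a tag path."""
    key = tuple(zlib.crc32(t.encode()) if isinstance(t, str) else int(t) for t in tags)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
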