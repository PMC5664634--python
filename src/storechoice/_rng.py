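"""Named random substreams.

A single user-facing seed governs every draw in the package; each operation
pulls an independent generator keyed by (seed, crc32(name)), so re-running any
pipeline stage in isolation reproduces exactly the draws it made in a full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named substream generator for a given base seed."""
    entropy = (int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, index: int) -> int:
    """Derive a reproducible integer child seed (< 2**31) for replicate runs."""
    ss = np.random.SeedSequence((int(seed) & 0x7FFFFFFF, int(index)))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF
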