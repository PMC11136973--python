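"""Named random substreams derived from a single integer seed.

Every stochastic operation in the package draws from its own named
substream so that component-level results are reproducible independently
of the order in which other components consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of ``seed``."""
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit integer seed (for libraries that take int seeds)."""
    return int(rng.integers(2**31 - 1))
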