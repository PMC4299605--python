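"""Named random substreams derived from a single master seed.

Every stochastic stage (cross, expression, reads, calls, forests,
permutations, ...) draws from its own named substream so that stages are
independently reproducible: re-running one stage with the same master seed
yields the same numbers regardless of what other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_int_seed"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of master ``seed``."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def child_int_seed(rng: np.random.Generator) -> int:
    """Draw a small integer seed (< 2**31) for libraries wanting an int state."""
    return int(rng.integers(0, 2**31 - 1))
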