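"""Seeded RNG substreams.

Every stage that consumes randomness draws from a named substream derived from
the single pipeline seed, so inserting or reordering stages never perturbs the
random numbers another stage sees.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator keyed by (seed, stage name)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
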