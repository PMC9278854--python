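"""Deterministic random-stream management.

One master seed fans out to named substreams so that re-running a single
pipeline stage never perturbs the random draws of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a stream name."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator for the named substream of ``seed``."""
    return np.random.default_rng(child_seed(seed, name))
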