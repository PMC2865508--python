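"""Seed plumbing: every stage derives its generator from one top-level seed.

Substreams are named, so adding a stage never perturbs the randomness another
stage consumes, and no code in the package touches the global NumPy state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_rng"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so the mapping is stable across
    runs, platforms, and Python hash randomization.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept a seed, a Generator, or None (fresh entropy) and return a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
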