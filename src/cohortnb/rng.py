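"""Seeded randomness: one global integer seed drives a hierarchy of named
independent streams (one per module/sub-pipeline), so a sub-pipeline run in
isolation with the same seed reproduces bit-identically."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named random stream derived from the global seed.

    The stream for a given (seed, name) pair is stable across processes and
    platforms; distinct names give statistically independent streams.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
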