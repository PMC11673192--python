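"""Seed fan-out and small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Derive an independent generator for a named component from one global seed.

    The name is hashed with CRC32 so the stream depends only on (seed, name),
    never on call order — components stay individually reproducible.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))


def round_half_up(x: float) -> int:
    """Round with ties going up (3 for 2.5), unlike banker's rounding."""
    return int(np.floor(x + 0.5))
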