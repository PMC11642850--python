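"""Seed-derivation helpers.

All stochastic functions in the package derive their generators from a
single integer master seed through :func:`numpy.random.SeedSequence` with a
structured ``spawn_key``, so that any subset of the simulation (one cell, one
analyte, one repetition) is independently reproducible without replaying the
whole stream.  String path components are mapped to integers with CRC-32,
which is stable across platforms and Python versions.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def _as_key(part: int | str) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    return int(part)


def child_seed_sequence(master_seed: int, *path: int | str) -> np.random.SeedSequence:
    """SeedSequence for a node addressed by ``path`` under ``master_seed``."""
    return np.random.SeedSequence(int(master_seed), spawn_key=tuple(_as_key(p) for p in path))


def child_rng(master_seed: int, *path: int | str) -> np.random.Generator:
    """Independent Generator for a node addressed by ``path``."""
    return np.random.default_rng(child_seed_sequence(master_seed, *path))
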