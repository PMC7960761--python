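"""Seed plumbing: one global seed, named substreams per stage.

Every random draw in the package flows from a single integer seed through
``substream(seed, name)``, so any stage can be re-run in isolation and
reproduce its output bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_name_key(name),)))


def substream_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for stages that take plain seeds."""
    return int(np.random.SeedSequence(int(seed), spawn_key=(_name_key(name),)).generate_state(1)[0] % (2**31))
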