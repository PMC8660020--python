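"""Deterministic seed fan-out.

One user-facing integer seed is split into independent child streams keyed
by short strings (generator name, comparison key, ...), so adding a stream
never shifts the draws of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _key_int(key: str) -> int:
    """Stable 32-bit digest of a string key."""
    return int.from_bytes(hashlib.blake2s(key.encode()).digest()[:4], "little")


def child_seed(seed: int, *keys: str) -> np.random.SeedSequence:
    """SeedSequence derived from (seed, keys), order-sensitive and stable."""
    return np.random.SeedSequence([int(seed) % (2**31)] + [_key_int(k) for k in keys])


def child_rng(seed: int, *keys: str) -> np.random.Generator:
    """Generator on the child stream named by ``keys``."""
    return np.random.default_rng(child_seed(seed, *keys))
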