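"""Shared helpers: seeding, validation, logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("metbmikit")


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a child seed from a master seed and a stable token sequence.

    Uses CRC32 of the token string mixed with the master seed so that
    per-stage / per-item streams are decoupled but fully reproducible.
    The result is always in [0, 2**31).
    """
    label = "|".join(str(t) for t in tokens)
    h = zlib.crc32(label.encode("utf-8"))
    mixed = ((int(master_seed) * 2654435761) & 0xFFFFFFFF) ^ h
    return mixed % 2**31


def check_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr
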