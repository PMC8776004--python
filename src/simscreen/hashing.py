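"""Deterministic 32-bit hashing used by every hashed fingerprint.

All hashed fingerprints (path-based, extended-connectivity, 2D pharmacophore,
3D shells) route through FNV-1a over a little-endian byte encoding of their
token streams.  The dialect is pinned: changing it changes every stored
fingerprint, so it is frozen here and nowhere else.
"""

from __future__ import annotations

import struct
from collections.abc import Iterable

FNV_OFFSET = 0x811C9DC5
FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF


def fnv1a(data: bytes, seed: int = FNV_OFFSET) -> int:
    """FNV-1a over raw bytes, 32-bit."""
    h = seed & _MASK32
    for byte in data:
        h ^= byte
        h = (h * FNV_PRIME) & _MASK32
    return h


def hash_ints(values: Iterable[int], seed: int = FNV_OFFSET) -> int:
    """Hash a sequence of integers reduced to 32 bits (little-endian packed)."""
    packed = b"".join(struct.pack("<I", v & _MASK32) for v in values)
    return fnv1a(packed, seed)


def hash_str(text: str, seed: int = FNV_OFFSET) -> int:
    return fnv1a(text.encode("utf-8"), seed)
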