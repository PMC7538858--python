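"""Small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np

_MIX_A = 0x9E3779B9  # golden-ratio constant, splitmix-style diffusion
_MOD = 2**31 - 1


def mix_seed(seed: int, index: int) -> int:
    """Derive a child seed below 2**31 from (seed, index) via a fixed integer mix.

    Used wherever one user-facing seed must fan out into independent
    per-patient / per-realization streams reproducibly.
    """
    x = (int(seed) & 0xFFFFFFFF) ^ ((int(index) * _MIX_A) & 0xFFFFFFFF)
    x = (x ^ (x >> 16)) * 0x45D9F3B & 0xFFFFFFFF
    x = (x ^ (x >> 16)) * 0x45D9F3B & 0xFFFFFFFF
    x ^= x >> 16
    return x % _MOD


def stable_str_seed(seed: int, key: str) -> int:
    """Deterministic seed derived from an integer seed and a string key."""
    return mix_seed(seed, zlib.crc32(key.encode("utf-8")))


def as_bool_mask(arr, name: str = "mask") -> np.ndarray:
    """Validate a 2-D binary array and return it as bool."""
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {a.shape}")
    if a.dtype == bool:
        return a
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0,1}}), found {vals[:5]}")
    return a.astype(bool)
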