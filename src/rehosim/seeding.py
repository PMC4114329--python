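"""Stable seed derivation.

Replicate and per-subject random streams are derived from a master seed by
hashing the identifying context (study name, subject index, train size,
replicate id) with SHA-256, so any single subject or replicate can be
regenerated in isolation and results are reproducible across platforms and
process restarts (unlike the builtin ``hash``, which is salted).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(*parts) -> int:
    """Deterministic 31-bit seed from an arbitrary tuple of ints/strings."""
    payload = "\x1f".join(repr(p) for p in parts).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def derive_rng(*parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(*parts))
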