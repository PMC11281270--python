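"""Deterministic random-stream derivation.

All randomness in the package flows from a single master seed. Substreams
are derived by stable hashing of (seed, *tokens) so that, e.g., subject
"s03" always receives the same stream regardless of how many subjects are
simulated before it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, *tokens: object) -> int:
    """Derive a stable 63-bit child seed from a master seed and tokens."""
    key = ":".join([str(int(seed))] + [str(t) for t in tokens])
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") & 0x7FFF_FFFF_FFFF_FFFF


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """A numpy Generator seeded from a hashed (seed, tokens) key."""
    return np.random.default_rng(child_seed(seed, *tokens))
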