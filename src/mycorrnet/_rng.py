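"""Deterministic seed derivation.

Every stochastic stage derives per-unit child seeds from a master seed plus a
stable key (a sample id, a forest id, a permutation index).  Keys are hashed,
not enumerated positionally, so results are invariant to the order in which
rows happen to be stored and to whether permutations run serially or in
parallel.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MASK32 = 0xFFFFFFFF


def child_seed_sequence(master: int, *keys: int | str) -> np.random.SeedSequence:
    """Build a SeedSequence from a master seed and a stable key path.

    String keys are hashed with SHA-256 (Python's builtin ``hash`` is salted
    per process and therefore unusable); integer keys are used directly.
    """
    words: list[int] = [int(master) & _MASK32]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            words.append(int(key) & _MASK32)
        else:
            digest = hashlib.sha256(str(key).encode("utf-8")).digest()
            words.extend(
                int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)
            )
    return np.random.SeedSequence(words)


def child_rng(master: int, *keys: int | str) -> np.random.Generator:
    """Generator seeded by :func:`child_seed_sequence`."""
    return np.random.default_rng(child_seed_sequence(master, *keys))
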