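"""Deterministic seeding helpers.

One global integer seed drives every generator; sub-generators derive child
seeds from (seed, *string keys) so that stages can be re-run in isolation
without perturbing each other's streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, *keys: str | int) -> np.random.SeedSequence:
    """Derive a reproducible child SeedSequence from a root seed and keys.

    String keys are hashed with crc32 so the derivation is stable across
    processes and Python versions (unlike ``hash``).
    """
    entropy = [int(seed)]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode("utf-8")))
        else:
            entropy.append(int(k))
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """A Generator seeded deterministically from (seed, *keys)."""
    return np.random.default_rng(child_seed(seed, *keys))
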