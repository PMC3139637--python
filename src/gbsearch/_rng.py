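"""Deterministic seed fan-out.

One master seed is expanded into independent substreams keyed by structured
labels (replicate, group, game, agent index, ...).  Because each stream is
derived from the key alone, adding or removing a group never perturbs the
draws of any other group — a property the regression tests rely on.
"""

from __future__ import annotations

import hashlib
import random

__all__ = ["derive_seed", "substream"]


def derive_seed(master: int, *keys: object) -> int:
    """Derive a 63-bit child seed from a master seed and a key path."""
    material = repr((int(master),) + tuple(keys)).encode()
    digest = hashlib.blake2b(material, digest_size=8).digest()
    return int.from_bytes(digest, "big") >> 1


def substream(master: int, *keys: object) -> random.Random:
    """A ``random.Random`` generator seeded from ``derive_seed``."""
    return random.Random(derive_seed(master, *keys))
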