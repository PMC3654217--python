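"""Deterministic seed derivation.

All randomness in the package flows from one root seed. Component streams
are derived from it with stable string labels, so every stage of a pipeline
is independently reproducible: ``derive_rng(seed, "reads", site)`` yields
the same generator no matter what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(root_seed: int, *labels: object) -> np.random.Generator:
    """Generator for the component stream named by ``labels``."""
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=key)
    return np.random.default_rng(ss)


def derive_seed(root_seed: int, *labels: object) -> int:
    """A plain integer seed (< 2**31) for the named component stream."""
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
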