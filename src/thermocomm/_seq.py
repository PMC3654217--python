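"""Low-level DNA sequence helpers shared across modules.

Sequences are plain Python strings (upper-case) at module boundaries and
int8 arrays (A=0, C=1, G=2, T=3, anything else = -1) internally.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes; non-ACGT characters become -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """IID random sequence with expected G+C fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p))
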