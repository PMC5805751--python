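"""Nucleotide encodings shared across the package.

Bases are coded A=0, C=1, G=2, T=3; anything else (N, gaps) is 4.
"""

from __future__ import annotations

import numpy as np

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODE = np.full(256, 4, dtype=np.int8)
for _c, _i in NT_INDEX.items():
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes; non-ACGT characters map to 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def context_index(codes: np.ndarray) -> int:
    """Base-4 integer index of a context (leftmost base = most significant)."""
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def all_context_digits(width: int) -> np.ndarray:
    """(4**width, width) int8 array: row k = base-4 digits of k."""
    n = 4**width
    out = np.empty((n, width), dtype=np.int8)
    k = np.arange(n)
    for pos in range(width):
        out[:, width - 1 - pos] = (k >> (2 * pos)) & 3
    return out
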