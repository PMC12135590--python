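"""Low-level k-mer machinery: 2-bit encoding, canonicalisation, vectorised window counting.

k-mers are packed into uint64 codes with the leftmost base in the highest
bits, so numeric order on codes equals lexicographic order on the strings.
k is restricted to odd values <= 31 elsewhere, hence 2(k+1) <= 64 bits always
fits a (k+1)-mer code.
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code; anything that is not ACGT maps to the sentinel 4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to a uint8 array of 2-bit codes (4 = ambiguous)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_codes(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes of all length-k windows of ``bases`` plus a validity mask.

    Windows containing an ambiguous base are flagged invalid; their code is
    meaningless.  Runs in O(k) vectorised passes over the array.
    """
    n = bases.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    two_bit = (bases & np.uint8(3)).astype(np.uint64)
    comp = np.uint64(3) - two_bit
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd |= two_bit[j : j + m] << np.uint64(2 * (k - 1 - j))
        rev |= comp[j : j + m] << np.uint64(2 * j)
    ambig = np.concatenate(([0], np.cumsum(bases == 4)))
    valid = (ambig[k:] - ambig[:-k]) == 0
    return np.minimum(fwd, rev), valid


def decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """Unpack uint64 k-mer codes back to DNA strings (vectorised)."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        out[:, j] = _CODE_BASE[
            ((codes >> np.uint64(2 * (k - 1 - j))) & np.uint64(3)).astype(np.uint8)
        ]
    flat = out.tobytes()
    return [flat[i * k : (i + 1) * k].decode("ascii") for i in range(codes.size)]
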