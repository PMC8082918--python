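"""Vectorized 2-bit DNA encoding and k-mer code extraction.

Shared by the exact-match engine and the k-mer counters. Non-ACGT characters
encode as -1 and invalidate every k-mer window that contains them.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Per-base codes A=0 C=1 G=2 T=3, -1 for anything else (int8)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid): uint64 k-mer codes at every position, validity mask.

    Codes at invalid positions are arbitrary and must be masked by ``valid``.
    Requires k <= 32.
    """
    if k > 32:
        raise ValueError("k must be <= 32 for 2-bit packing")
    m = codes.size - k + 1
    if m <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    kc = np.zeros(m, np.uint64)
    valid = np.ones(m, bool)
    two = np.uint64(2)
    for j in range(k):
        c = codes[j : j + m]
        kc = (kc << two) | np.where(c >= 0, c, 0).astype(np.uint64)
        valid &= c >= 0
    return kc, valid


def rc_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """uint64 codes of the reverse complement of each k-mer window (position-aligned)."""
    m = codes.size - k + 1
    comp = np.where(codes >= 0, 3 - codes, 0)
    rc = np.zeros(max(m, 0), np.uint64)
    two = np.uint64(2)
    for j in range(k):
        c = comp[k - 1 - j : k - 1 - j + m]
        rc = (rc << two) | c.astype(np.uint64)
    return rc


def canonical_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-independent) k-mer codes: min(forward, reverse complement)."""
    fwd, valid = kmer_codes(codes, k)
    if fwd.size == 0:
        return fwd, valid
    rc = rc_kmer_codes(codes, k)
    return np.minimum(fwd, rc), valid


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))
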