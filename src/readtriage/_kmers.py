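"""Integer k-mer encoding shared by the mapper and the similarity stage.

Bases are 2-bit encoded (A=0, C=1, G=2, T=3); N gets code 4 and poisons any
k-mer window containing it. Canonical form is the lexicographic minimum of a
k-mer and its reverse complement, computed on the integer codes.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """2-bit codes per base (N and anything else → 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer integer codes at every offset, plus a validity mask.

    Returns ``(values, valid)`` of length ``len(codes) - k + 1``; positions
    whose window contains a non-ACGT base are masked invalid.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=np.int64)
    for i in range(k):
        window = codes[i : i + n]
        vals = (vals << 2) | (window & 3)
        bad += window == 4
    return vals, bad == 0


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


def canonical_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer codes at every offset.

    Returns ``(canonical, valid, is_forward)`` where ``is_forward[i]`` is True
    when the forward k-mer equals the canonical form.
    """
    fwd, valid = kmer_codes(codes, k)
    rc_all = revcomp_codes(codes)
    rev, _ = kmer_codes(rc_all, k)
    # reverse-complement of the k-mer starting at i is the k-mer starting at
    # n-k-i of the reverse-complemented sequence
    rev = rev[::-1]
    is_fwd = fwd <= rev
    canon = np.where(is_fwd, fwd, rev)
    return canon, valid, is_fwd


def canonical_kmer_set(seqs, k: int) -> set[int]:
    """Pooled canonical k-mers of an iterable of sequences (N-containing skipped)."""
    out: set[int] = set()
    for seq in seqs:
        canon, valid, _ = canonical_kmer_codes(encode(seq), k)
        out.update(canon[valid].tolist())
    return out
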