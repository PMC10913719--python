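"""Batched 2-bit k-mer machinery.

All heavy sequence work in the package funnels through this module.
Sequences are encoded over {A:0, C:1, G:2, T:3} as uint8 arrays, k-mers are
packed into uint64 codes (2 bits per base, so k <= 31), and set membership is
answered with searchsorted lookups against sorted code arrays.  Reads of
mixed length are processed in equal-length groups so every inner loop is a
numpy vector operation.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode one sequence as a uint8 vector; raises on non-ACGT bases."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return arr


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Rows of a 2-bit matrix back to ACGT strings."""
    ascii_mat = _BASES[mat]
    n, length = ascii_mat.shape
    buf = ascii_mat.tobytes()
    return [buf[i * length : (i + 1) * length].decode("ascii") for i in range(n)]


def group_by_length(seqs: Sequence[str]) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (indices, encoded matrix) per distinct sequence length.

    Indices refer back to positions in ``seqs``; empty sequences are skipped.
    """
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    for length in np.unique(lengths):
        if length == 0:
            continue
        idx = np.nonzero(lengths == length)[0]
        buf = "".join(seqs[i] for i in idx).encode("ascii")
        mat = _LUT[np.frombuffer(buf, dtype=np.uint8)].reshape(len(idx), length)
        yield idx, mat


def kmer_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Forward-strand k-mer codes, shape (n_reads, L - k + 1).

    Rolling update along the sequence axis keeps the work at O(n * L)
    regardless of k.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31] to fit a uint64 code")
    n, length = mat.shape
    w = length - k + 1
    if w <= 0:
        return np.empty((n, 0), dtype=np.uint64)
    m = mat.astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    two = np.uint64(2)
    out = np.empty((n, w), dtype=np.uint64)
    code = np.zeros(n, dtype=np.uint64)
    for j in range(k - 1):
        code = (code << two) | m[:, j]
    for p in range(w):
        code = ((code << two) | m[:, p + k - 1]) & mask
        out[:, p] = code
    return out


def canonical_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical (min of strand and reverse complement) k-mer codes."""
    fwd = kmer_codes(mat, k)
    rc_mat = (3 - mat)[:, ::-1]
    rc = kmer_codes(np.ascontiguousarray(rc_mat), k)[:, ::-1]
    return np.minimum(fwd, rc)


def seq_canonical_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes of a single sequence (1-D, possibly empty)."""
    if len(seq) < k:
        return np.empty(0, dtype=np.uint64)
    return canonical_codes(encode(seq)[None, :], k)[0]


def unique_canonical_codes(seqs: Iterable[str], k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes over a collection of sequences."""
    parts = [seq_canonical_codes(s, k) for s in seqs]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def member_mask(sorted_codes: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Boolean membership of ``queries`` in a sorted code array."""
    if sorted_codes.size == 0:
        return np.zeros(queries.shape, dtype=bool)
    pos = np.searchsorted(sorted_codes, queries)
    pos_c = np.minimum(pos, sorted_codes.size - 1)
    return sorted_codes[pos_c] == queries


class CodeTable:
    """Sorted canonical-code array with an integer value per code."""

    def __init__(self, codes: np.ndarray, values: np.ndarray):
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.values = values[order]

    def lookup(self, queries: np.ndarray, default: int = -1) -> np.ndarray:
        """Value per query, ``default`` where the code is absent."""
        out = np.full(queries.shape, default, dtype=self.values.dtype)
        if self.codes.size == 0:
            return out
        pos = np.searchsorted(self.codes, queries)
        pos_c = np.minimum(pos, self.codes.size - 1)
        hit = self.codes[pos_c] == queries
        out[hit] = self.values[pos_c[hit]]
        return out


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]
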