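"""Fixed-length nucleotide sequences as numpy byte arrays.

RAD tags are fixed-length 59-mers, so everything downstream of the FASTQ
parser works on rectangular ``uint8`` arrays of ASCII codes (one row per
sequence).  This keeps demultiplexing, unique-tag counting and Hamming
comparisons vectorised.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
_COMPLEMENT[np.frombuffer(b"ACGTN", dtype=np.uint8)] = np.frombuffer(
    b"TGCAN", dtype=np.uint8
)


def encode(seq: str) -> np.ndarray:
    """ASCII-encode one sequence to a 1-D uint8 array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def encode_many(seqs) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    data = "".join(s.upper() for s in seqs).encode("ascii")
    arr = np.frombuffer(data, dtype=np.uint8)
    return arr.reshape(len(seqs), -1).copy()


def decode(row: np.ndarray) -> str:
    return row.tobytes().decode("ascii")


def decode_rows(arr: np.ndarray) -> list[str]:
    n, length = arr.shape
    flat = arr.tobytes().decode("ascii")
    return [flat[i * length : (i + 1) * length] for i in range(n)]


def random_seqs(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Uniform random ACGT sequences as an (n, length) uint8 matrix."""
    return BASES[rng.integers(0, 4, size=(n, length))]


def revcomp_rows(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[:, ::-1]]


def is_acgt_rows(arr: np.ndarray) -> np.ndarray:
    """Boolean mask of rows containing only A/C/G/T."""
    ok = np.zeros(256, dtype=bool)
    ok[BASES] = True
    return ok[arr].all(axis=1)


def rows_as_void(arr: np.ndarray) -> np.ndarray:
    """View each row as one opaque item so np.unique can hash whole rows."""
    arr = np.ascontiguousarray(arr)
    return arr.view([("", np.void, arr.shape[1])]).ravel()


def _row_hashes(arr: np.ndarray) -> np.ndarray:
    """64-bit multiply-add hash per row (vectorised column sweep)."""
    rng = np.random.default_rng(0xC0FFEE)  # fixed multipliers: stable hashing
    mult = rng.integers(1, np.iinfo(np.int64).max, size=arr.shape[1], dtype=np.int64)
    mult |= 1  # odd multipliers mix better
    h = np.zeros(arr.shape[0], dtype=np.int64)
    with np.errstate(over="ignore"):
        for j in range(arr.shape[1]):
            h = h * np.int64(-7046029254386353131) + arr[:, j] * mult[j]
    return h


def _unique_rows_exact(arr: np.ndarray):
    void = rows_as_void(arr)
    _, first, inverse, counts = np.unique(
        void, return_index=True, return_inverse=True, return_counts=True
    )
    return arr[first], inverse, counts


def unique_rows(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique rows (lexicographically sorted), inverse indices and counts.

    Rows are first grouped by a 64-bit hash (much faster than sorting the
    raw byte rows); the grouping is then verified row-by-row against the
    group representatives and falls back to an exact byte-wise unique in
    the (astronomically unlikely) event of a hash collision.
    """
    if arr.shape[0] == 0:
        return arr.copy(), np.zeros(0, dtype=np.intp), np.zeros(0, dtype=np.int64)
    h = _row_hashes(arr)
    _, first, inverse, counts = np.unique(
        h, return_index=True, return_inverse=True, return_counts=True
    )
    reps = arr[first]
    if (arr != reps[inverse]).any():  # hash collision: exact fallback
        return _unique_rows_exact(arr)
    # re-sort representatives lexicographically for deterministic output
    order = np.argsort(rows_as_void(reps), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return reps[order], rank[inverse], counts[order]


def hamming_matrix(a: np.ndarray, b: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Pairwise Hamming distances between rows of ``a`` and rows of ``b``."""
    out = np.empty((a.shape[0], b.shape[0]), dtype=np.int16)
    for start in range(0, a.shape[0], chunk):
        block = a[start : start + chunk]
        out[start : start + chunk] = (block[:, None, :] != b[None, :, :]).sum(
            axis=2, dtype=np.int16
        )
    return out
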