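"""Suffix-array primitives shared by the match-finding modules.

The index is an enhanced suffix array (suffix array + LCP array) built
over an integer encoding in which A,C,G,T map to 1..4 and every other
position -- N bases, contig separators, end-of-sequence terminators --
receives its own globally unique code.  That encoding makes N never match
anything (including another N) and keeps matches from crossing contig or
sequence boundaries, without any special-casing in the scan itself.
"""

from __future__ import annotations

import numpy as np

_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}
_UNIQUE_START = 5


def encode(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into one integer array with unique terminators.

    Returns (codes, starts) where ``starts[i]`` is the offset of sequence
    ``i``; each sequence is followed by one terminator position, so the
    slot for sequence i spans ``starts[i] .. starts[i] + len(seqs[i])``.
    """
    total = sum(len(s) for s in seqs) + len(seqs)
    codes = np.empty(total, dtype=np.int64)
    starts = np.empty(len(seqs), dtype=np.int64)
    nxt = _UNIQUE_START
    pos = 0
    lut = np.full(128, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    for i, s in enumerate(seqs):
        starts[i] = pos
        arr = lut[np.frombuffer(s.encode("latin-1"), dtype=np.uint8)]
        unk = np.nonzero(arr < 0)[0]
        if unk.size:
            arr[unk] = np.arange(nxt, nxt + unk.size)
            nxt += unk.size
        codes[pos:pos + len(s)] = arr
        pos += len(s)
        codes[pos] = nxt  # terminator
        nxt += 1
        pos += 1
    return codes, starts


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized)."""
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    if rank[sa[-1]] == n - 1:
        return sa
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed)
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def _lcp_kasai_py(codes, sa, rank):
    n = len(sa)
    lcp = [0] * n
    h = 0
    c = codes
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            m = n
            while i + h < m and j + h < m and c[i + h] == c[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def _kasai_kernel(codes, sa, rank, lcp):  # pragma: no cover - numba body
    n = sa.shape[0]
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
            lcp[r] = 0
    return lcp


try:  # optional compiled fast path for large inputs
    from numba import njit as _njit

    _lcp_kasai_nb = _njit(cache=True, nogil=True)(_kasai_kernel)
except Exception:  # pragma: no cover - numba absent or broken
    _lcp_kasai_nb = None


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array (Kasai); lcp[i] = lcp(suffix sa[i-1], suffix sa[i])."""
    n = sa.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    if _lcp_kasai_nb is not None and n > 50_000:
        lcp = np.zeros(n, dtype=np.int64)
        return np.asarray(_lcp_kasai_nb(codes, sa, rank, lcp))
    return np.asarray(
        _lcp_kasai_py(codes.tolist(), sa.tolist(), rank.tolist()),
        dtype=np.int64,
    )


def _pow_tables(a: np.ndarray, w: int, op) -> np.ndarray:
    """Sparse-table style sliding aggregate over windows of width w.

    Returns array r of length len(a) - w + 1 with r[i] = op over a[i:i+w].
    """
    n = a.size
    if w <= 1:
        return a.copy()
    r = a.copy()
    s = 1
    while s * 2 <= w:
        r = op(r[: r.size - s], r[s:])
        s *= 2
    if s < w:
        d = w - s
        r = op(r[: n - w + 1], r[d: d + n - w + 1])
    return r[: n - w + 1]


def sliding_min(a: np.ndarray, w: int) -> np.ndarray:
    return _pow_tables(a, w, np.minimum)


def sliding_max(a: np.ndarray, w: int) -> np.ndarray:
    return _pow_tables(a, w, np.maximum)


def sliding_or(a: np.ndarray, w: int) -> np.ndarray:
    return _pow_tables(a, w, np.bitwise_or)
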