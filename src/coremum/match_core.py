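"""Enumeration of matches that are maximal and unique in every sequence.

The scan builds one enhanced suffix array over the forward and
reverse-complement copies of all input sequences and slides a window of
width g (the number of sequences) over it.  A window whose suffixes come
from all g sequences, whose inner LCP minimum L is at least ``min_len``
and exceeds both boundary LCPs, is exactly the suffix-array interval of a
substring occurring once per sequence (counting both strands).  The inner
LCP minimum guarantees right-maximality; a preceding-character check
guarantees left-maximality.  With g = 2 this enumerates classical MUMs;
with g > 2, multi-MUMs.

Every match is reported twice by construction (once per strand of the
match substring); the scan keeps the copy in which sequence 0 -- the
reference -- occurs on its forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sa import encode, lcp_array, sliding_max, sliding_min, sliding_or, suffix_array
from .sequence_io import revcomp

#: doc-presence bitmask limit (int64); far above any sensible batch size
MAX_SEQS = 62


@dataclass(frozen=True)
class RawMatch:
    """A match unique in every input sequence.

    ``placements[i]`` is ``(start, reverse)`` for sequence i: the start of
    the matched substring on the sequence's forward strand, and whether
    the occurrence is on the reverse strand.  Sequence 0 is always
    forward.
    """

    length: int
    placements: tuple[tuple[int, bool], ...]


def scan_multimums(seqs: list[str], min_len: int) -> list[RawMatch]:
    """All maximal matches of length >= min_len unique in every sequence."""
    g = len(seqs)
    if g < 2:
        raise ValueError("need at least 2 sequences")
    if g > MAX_SEQS:
        raise ValueError(
            f"at most {MAX_SEQS} sequences per scan; use genome partitioning"
        )
    if min_len < 1:
        raise ValueError("min_len must be positive")

    texts = list(seqs) + [revcomp(s) for s in seqs]
    codes, starts = encode(texts)
    n = codes.size
    if n - 2 * g < min_len:  # not even one window possible
        return []
    sa = suffix_array(codes)
    lcp = lcp_array(codes, sa)

    # inner LCP minimum over lcp[i+1 .. i+g-1] for window start i
    L = sliding_min(lcp[1:], g - 1)[: n - g + 1]
    ok = L >= min_len
    # uniqueness: boundary LCPs strictly below the match length
    left_b = lcp[: n - g + 1] < L
    right_lcp = np.zeros(n - g + 1, dtype=lcp.dtype)
    right_lcp[: n - g] = lcp[g:]
    ok &= left_b & (right_lcp < L)

    # every sequence present exactly once in the window
    copy_of = np.searchsorted(starts, sa, side="right") - 1
    doc_of = copy_of % g
    bits = (np.int64(1) << doc_of.astype(np.int64))
    full = np.int64((1 << g) - 1)
    ok &= sliding_or(bits, g)[: n - g + 1] == full

    # left-maximality: not all preceding characters equal.  Codes >= 5 are
    # unique per occurrence, so equality can only happen on A,C,G,T.
    prev_code = np.where(
        sa > 0, codes[np.maximum(sa - 1, 0)], -(np.arange(n, dtype=np.int64) + 1)
    )
    all_eq = sliding_min(prev_code, g) == sliding_max(prev_code, g)
    ok &= ~all_eq[: n - g + 1]

    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return []

    local = sa - starts[copy_of]
    seq_lens = np.array([len(s) for s in seqs], dtype=np.int64)
    out: list[RawMatch] = []
    for i in idx:
        length = int(L[i])
        placements: list[tuple[int, bool] | None] = [None] * g
        ref_forward = True
        for j in range(i, i + g):
            d = int(doc_of[j])
            rev = copy_of[j] >= g
            if rev:
                start = int(seq_lens[d] - local[j] - length)
            else:
                start = int(local[j])
            if d == 0 and rev:
                ref_forward = False
                break
            placements[d] = (start, bool(rev))
        if not ref_forward:
            continue  # the reverse-complement twin window reports this match
        out.append(RawMatch(length=length, placements=tuple(placements)))
    out.sort(key=lambda m: (m.placements[0][0], -m.length))
    return out


def count_occurrences(text: str, pattern: str, both_strands: bool = True) -> int:
    """Overlap-aware occurrence count, optionally on both strands."""
    if not pattern:
        return 0

    def _count(t: str, p: str) -> int:
        c = 0
        i = t.find(p)
        while i != -1:
            c += 1
            i = t.find(p, i + 1)
        return c

    total = _count(text, pattern)
    if both_strands:
        total += _count(text, revcomp(pattern))
    return total
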