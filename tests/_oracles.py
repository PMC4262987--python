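"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid the suffix-array machinery: matches are found
by substring containment and overlap-aware counting on plain strings.
"""

from __future__ import annotations

from coremum.match_core import count_occurrences
from coremum.sequence_io import revcomp

_ACGT = set("ACGT")


def brute_multimums(seqs: list[str], min_len: int) -> set[tuple]:
    """All multi-MUMs as (length, ((start, reverse), ...)) with the
    occurrence in seqs[0] on the forward strand."""

    def present_everywhere(sub: str) -> bool:
        if not set(sub) <= _ACGT:
            return False  # N and separators never match
        return all(count_occurrences(s, sub) >= 1 for s in seqs)

    out = set()
    ref = seqs[0]
    n = len(ref)
    for i in range(n - min_len + 1):
        if not present_everywhere(ref[i:i + min_len]):
            continue
        lo, hi = min_len, n - i  # max l with presence in all genomes
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if present_everywhere(ref[i:i + mid]):
                lo = mid
            else:
                hi = mid - 1
        l = lo
        sub = ref[i:i + l]
        if any(count_occurrences(s, sub) != 1 for s in seqs):
            continue
        if i > 0 and ref[i - 1] in _ACGT and present_everywhere(ref[i - 1] + sub):
            continue  # not left-maximal; reported at i-1
        placements = []
        for s in seqs:
            j = s.find(sub)
            if j != -1:
                placements.append((j, False))
            else:
                placements.append((s.find(revcomp(sub)), True))
        out.add((l, tuple(placements)))
    return out


def brute_mums(a: str, b: str, min_len: int) -> set[tuple]:
    """Pairwise MUMs as (ref_start, qry_start, length, reverse)."""
    return {
        (pl[0][0], pl[1][0], length, pl[1][1])
        for length, pl in brute_multimums([a, b], min_len)
    }


def nw_affine_score(
    s1: str,
    s2: str,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = -12,
    gap_extend: int = -1,
) -> float:
    """Textbook Needleman-Wunsch with affine gaps (Gotoh).

    A gap of length k costs gap_open + (k-1) * gap_extend.  N matches
    nothing, including another N.
    """
    neg = float("-inf")
    n, m = len(s1), len(s2)

    def sub(x: str, y: str) -> int:
        return match if (x == y and x in _ACGT) else mismatch

    M = [neg] * (m + 1)
    X = [neg] * (m + 1)  # gap in s2 (vertical)
    Y = [neg] * (m + 1)  # gap in s1 (horizontal)
    M[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        prevM, prevX, prevY = M[:], X[:], Y[:]
        M = [neg] * (m + 1)
        X = [neg] * (m + 1)
        Y = [neg] * (m + 1)
        X[0] = gap_open + (i - 1) * gap_extend
        for j in range(1, m + 1):
            best_prev = max(prevM[j - 1], prevX[j - 1], prevY[j - 1])
            M[j] = best_prev + sub(s1[i - 1], s2[j - 1])
            X[j] = max(prevM[j] + gap_open, prevX[j] + gap_extend,
                       prevY[j] + gap_open)
            Y[j] = max(M[j - 1] + gap_open, Y[j - 1] + gap_extend,
                       X[j - 1] + gap_open)
    return max(M[m], X[m], Y[m])
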