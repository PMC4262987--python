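"""Suffix index over the reference genome and pairwise MUM search.

The index is realized as an enhanced suffix array (suffix array + LCP)
over the reference concatenation; its answer set is equivalent to a
suffix tree of the reference.  Queries are streamed against it one
genome at a time: :func:`stream_query` reports every maximal unique
match (MUM) between the reference and the query, searching the query in
both orientations and reporting reverse-match coordinates on the query's
forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._sa import encode, lcp_array, suffix_array
from .errors import NoIndexableSequenceError
from .match_core import scan_multimums
from .sequence_io import Genome

DEFAULT_MIN_ANCHOR = 21


@dataclass(frozen=True)
class PairMatch:
    """A MUM between reference and query.

    ``qry_start`` is on the query's forward strand regardless of
    orientation; ``reverse`` marks a reverse-strand query occurrence.
    """

    ref_start: int
    qry_start: int
    length: int
    reverse: bool


class SuffixIndex:
    """Enhanced suffix array over the reference concatenation."""

    def __init__(self, reference: Genome, min_anchor_length: int = DEFAULT_MIN_ANCHOR):
        if reference.concat_length == 0:
            raise NoIndexableSequenceError("empty reference")
        if not any(c in "ACGT" for c in reference.concat):
            raise NoIndexableSequenceError(
                f"reference {reference.id!r} contains no indexable sequence"
            )
        self.reference = reference
        self.min_anchor_length = int(min_anchor_length)
        self._codes, _ = encode([reference.concat])
        self._sa = suffix_array(self._codes)
        self._lcp = lcp_array(self._codes, self._sa)

    # -- direct substring queries (used for validation and small tools) --

    def count(self, pattern: str) -> int:
        """Number of forward-strand occurrences of pattern in the reference.

        Patterns containing N or a contig separator never match.
        """
        if not pattern or any(c not in "ACGT" for c in pattern):
            return 0
        text = self.reference.concat
        sa = self._sa
        m = len(pattern)

        def _suffix(i: int) -> str:
            p = int(sa[i])
            return text[p:p + m]

        lo, hi = 0, len(sa)
        while lo < hi:  # leftmost suffix >= pattern
            mid = (lo + hi) // 2
            if _suffix(mid) < pattern:
                lo = mid + 1
            else:
                hi = mid
        first = lo
        lo, hi = first, len(sa)
        while lo < hi:  # leftmost suffix > pattern prefix
            mid = (lo + hi) // 2
            if _suffix(mid) <= pattern:
                lo = mid + 1
            else:
                hi = mid
        return lo - first

    def is_unique(self, pattern: str) -> bool:
        return self.count(pattern) == 1


def build_index(reference: Genome, min_anchor_length: int = DEFAULT_MIN_ANCHOR) -> SuffixIndex:
    """Build the reference suffix index."""
    return SuffixIndex(reference, min_anchor_length)


def stream_query(
    index: SuffixIndex, query: Genome, min_len: int | None = None
) -> list[PairMatch]:
    """All MUMs (unique in reference and query, both strands, maximal)
    of length >= min_len, sorted by reference start."""
    if query.concat_length == 0:
        raise NoIndexableSequenceError("empty query")
    if min_len is None:
        min_len = index.min_anchor_length
    raw = scan_multimums([index.reference.concat, query.concat], min_len)
    out = [
        PairMatch(
            ref_start=m.placements[0][0],
            qry_start=m.placements[1][0],
            length=m.length,
            reverse=m.placements[1][1],
        )
        for m in raw
    ]
    out.sort(key=lambda pm: (pm.ref_start, pm.qry_start))
    return out
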