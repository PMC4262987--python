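"""Multi-MUM search: matches unique in every genome, refined recursively.

A multi-MUM is an exact match occurring exactly once in each genome of
the run (counting both strands) that cannot be extended in either
direction without breaking the match or its uniqueness.  The initial
search runs over whole genomes; :func:`recursive_refine` then re-searches
the unanchored regions between consecutive anchors with the minimum
length halved per level (never below a floor), with uniqueness required
only within the bounded region.

Genome partitioning bounds the number of genomes per suffix-array scan:
multi-MUMs are computed per batch against the shared reference and then
intersected, which may split anchors but never extends them.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

from .match_core import RawMatch, count_occurrences, scan_multimums
from .sequence_io import Genome, revcomp

log = logging.getLogger(__name__)

DEFAULT_REFINE_FLOOR = 12


@dataclass(frozen=True)
class MultiMUM:
    """An exact match placed exactly once in every genome.

    ``placements`` maps genome id to ``(start, reverse)`` with the start
    on the genome's forward strand; the reference is always forward.
    """

    length: int
    placements: dict[str, tuple[int, bool]]

    def start(self, gid: str) -> int:
        return self.placements[gid][0]

    def end(self, gid: str) -> int:
        return self.placements[gid][0] + self.length

    def is_reverse(self, gid: str) -> bool:
        return self.placements[gid][1]

    def trimmed(self, dl: int, dr: int) -> "MultiMUM":
        """Trim dl columns from the alignment-left end and dr from the
        alignment-right end (reference orientation)."""
        new_len = self.length - dl - dr
        if new_len <= 0:
            raise ValueError("trimmed to nothing")
        placements = {}
        for gid, (s, rev) in self.placements.items():
            placements[gid] = (s + (dr if rev else dl), rev)
        return MultiMUM(length=new_len, placements=placements)


def _from_raw(raw: RawMatch, ids: list[str]) -> MultiMUM:
    return MultiMUM(
        length=raw.length,
        placements={gid: raw.placements[i] for i, gid in enumerate(ids)},
    )


def _trim_to_nonoverlapping(matches: list[MultiMUM], ref_id: str) -> list[MultiMUM]:
    """Make reference extents non-overlapping: longest anchor first, ties
    by leftmost reference start; later anchors are trimmed to the longest
    free stretch they still cover."""
    order = sorted(matches, key=lambda m: (-m.length, m.start(ref_id)))
    kept_starts: list[int] = []
    kept_ends: list[int] = []
    out: list[MultiMUM] = []
    for m in order:
        s, e = m.start(ref_id), m.end(ref_id)
        # collect kept intervals overlapping [s, e)
        i = bisect_right(kept_starts, s) - 1
        if i >= 0 and kept_ends[i] <= s:
            i += 1
        elif i < 0:
            i = 0
        free: list[tuple[int, int]] = []
        cur = s
        j = i
        while j < len(kept_starts) and kept_starts[j] < e:
            if kept_starts[j] > cur:
                free.append((cur, kept_starts[j]))
            cur = max(cur, kept_ends[j])
            j += 1
        if cur < e:
            free.append((cur, e))
        if not free:
            continue
        fs, fe = max(free, key=lambda iv: (iv[1] - iv[0], -iv[0]))
        if fe - fs < 1:
            continue
        if (fs, fe) != (s, e):
            m = m.trimmed(fs - s, e - fe)
        k = bisect_right(kept_starts, fs)
        kept_starts.insert(k, fs)
        kept_ends.insert(k, fe)
        out.append(m)
    out.sort(key=lambda m: m.start(ref_id))
    return out


def find_multimums(
    genomes: list[Genome],
    reference: Genome,
    min_len: int,
    trim: bool = True,
) -> list[MultiMUM]:
    """Multi-MUMs across the reference and all genomes, sorted by
    reference position; overlapping anchors on the reference are trimmed
    to be non-overlapping (longest-first, ties leftmost)."""
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    order = [reference] + [g for g in genomes if g.id != reference.id]
    if len(order) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.id for g in order]
    raw = scan_multimums([g.concat for g in order], min_len)
    matches = [_from_raw(r, ids) for r in raw]
    if trim:
        matches = _trim_to_nonoverlapping(matches, reference.id)
    else:
        matches.sort(key=lambda m: m.start(reference.id))
    return matches


# ---------------------------------------------------------------------------
# recursive refinement
# ---------------------------------------------------------------------------

def pair_gaps(
    prev: MultiMUM,
    nxt: MultiMUM,
    gids: list[str],
    max_gap: int,
    max_diag_diff: int | None = None,
) -> dict[str, int] | None:
    """Per-genome gap lengths between two reference-consecutive anchors.

    None when order/orientation is inconsistent in any genome, a gap
    exceeds max_gap, or (when max_diag_diff is set) the gap lengths
    disagree across genomes by more than max_diag_diff -- a long
    unanchored insertion in one genome is not core-alignable.
    """
    gaps: dict[str, int] = {}
    for gid in gids:
        ps, prev_rev = prev.placements[gid]
        ns, next_rev = nxt.placements[gid]
        if prev_rev != next_rev:
            return None
        if not prev_rev:
            gap = ns - (ps + prev.length)
        else:
            gap = ps - (ns + nxt.length)
        if gap < 0 or gap > max_gap:
            return None
        gaps[gid] = gap
    if max_diag_diff is not None:
        vals = gaps.values()
        if max(vals) - min(vals) > max_diag_diff:
            return None
    return gaps


def _refine_region(
    seqs: list[str], min_len: int, floor: int
) -> list[tuple[int, list[int]]]:
    """Region-scoped multi-MUMs, all-forward and collinear, as
    (length, per-sequence starts) in region coordinates."""
    shortest = min(len(s) for s in seqs)
    if shortest < floor:
        return []
    level = max(floor, min(min_len, shortest))
    raw = scan_multimums(seqs, level)
    cands = [
        (r.length, [p[0] for p in r.placements])
        for r in raw
        if not any(rev for _, rev in r.placements)
    ]
    cands.sort(key=lambda c: (c[1][0], -c[0]))
    kept: list[tuple[int, list[int]]] = []
    cursor = [0] * len(seqs)
    for length, starts in cands:
        if all(s >= c for s, c in zip(starts, cursor)):
            kept.append((length, starts))
            cursor = [s + length for s in starts]
    if not kept:
        return []
    if level > floor:
        # recurse into the gaps between the kept sub-anchors
        nxt_len = max(floor, level // 2)
        bounds_prev = [0] * len(seqs)
        extended: list[tuple[int, list[int]]] = []
        regions = []
        for k in range(len(kept) + 1):
            if k < len(kept):
                length, starts = kept[k]
                ends = starts
            else:
                ends = [len(s) for s in seqs]
            regions.append((list(bounds_prev), list(ends)))
            if k < len(kept):
                bounds_prev = [s + kept[k][0] for s in kept[k][1]]
        for lo, hi in regions:
            sub = [seqs[d][lo[d]:hi[d]] for d in range(len(seqs))]
            if min(len(s) for s in sub) < floor:
                continue
            for length, starts in _refine_region(sub, nxt_len, floor):
                extended.append((length, [s + lo[d] for d, s in enumerate(starts)]))
        kept = sorted(kept + extended, key=lambda c: c[1][0])
    return kept


def recursive_refine(
    genomes_by_id: dict[str, Genome],
    anchors: list[MultiMUM],
    min_len: int,
    floor: int = DEFAULT_REFINE_FLOOR,
    max_gap: int = 10_000,
) -> list[MultiMUM]:
    """Search the consistent inter-anchor regions for smaller anchors.

    The minimum match length halves per recursion level, never below
    ``floor``; uniqueness inside a region is region-scoped.
    """
    if floor < 8:
        raise ValueError("floor must be >= 8")
    if not anchors:
        return []
    gids = list(anchors[0].placements.keys())
    ref_id = gids[0]
    ordered = sorted(anchors, key=lambda m: m.start(ref_id))
    new: list[MultiMUM] = []
    first_level = max(floor, min_len // 2)
    if min_len <= floor:
        return ordered
    for a, b in zip(ordered, ordered[1:]):
        gaps = pair_gaps(a, b, gids, max_gap)
        if gaps is None or min(gaps.values()) < floor:
            continue
        regions: list[str] = []
        for gid in gids:
            gap = gaps[gid]
            s, rev = a.placements[gid]
            if not rev:
                lo = s + a.length
                regions.append(genomes_by_id[gid].concat[lo:lo + gap])
            else:
                bs, _ = b.placements[gid]
                lo = bs + b.length
                regions.append(revcomp(genomes_by_id[gid].concat[lo:lo + gap]))
        for length, starts in _refine_region(regions, first_level, floor):
            placements = {}
            for d, gid in enumerate(gids):
                s, rev = a.placements[gid]
                if not rev:
                    placements[gid] = (s + a.length + starts[d], False)
                else:
                    hi = s  # start of anchor a's forward interval
                    placements[gid] = (hi - starts[d] - length, True)
            new.append(MultiMUM(length=length, placements=placements))
    if new:
        log.info("recursive refinement added %d anchors", len(new))
    merged = ordered + new
    merged.sort(key=lambda m: m.start(ref_id))
    return merged


# ---------------------------------------------------------------------------
# genome partitioning
# ---------------------------------------------------------------------------

def partition_genomes(genomes: list[Genome], max_partition_size: int) -> list[list[Genome]]:
    """Split genomes into batches of at most max_partition_size."""
    if max_partition_size < 2:
        raise ValueError("max_partition_size must be >= 2")
    return [
        genomes[i:i + max_partition_size]
        for i in range(0, len(genomes), max_partition_size)
    ]


def partitioned_multimums(
    genomes: list[Genome],
    reference: Genome,
    max_partition_size: int,
    min_len: int,
) -> list[MultiMUM]:
    """Multi-MUMs computed per batch against the shared reference and
    intersected.  The intersection may split anchors, never extend them;
    fragments that lose all-genome uniqueness are dropped (logged)."""
    others = [g for g in genomes if g.id != reference.id]
    batches = partition_genomes(others, max_partition_size)
    if len(batches) <= 1:
        return find_multimums(others, reference, min_len)
    per_batch = [find_multimums(batch, reference, min_len) for batch in batches]
    ref_id = reference.id

    cuts: set[int] = set()
    for anchors in per_batch:
        for m in anchors:
            cuts.add(m.start(ref_id))
            cuts.add(m.end(ref_id))
    edges = sorted(cuts)

    # per batch: sorted anchor list for coverage lookup
    batch_starts = [[m.start(ref_id) for m in anchors] for anchors in per_batch]

    def covering(bi: int, x: int, y: int) -> MultiMUM | None:
        starts = batch_starts[bi]
        k = bisect_right(starts, x) - 1
        if k < 0:
            return None
        m = per_batch[bi][k]
        if m.start(ref_id) <= x and m.end(ref_id) >= y:
            return m
        return None

    all_genomes = [reference] + others
    fragments: list[MultiMUM] = []
    dropped = 0
    for x, y in zip(edges, edges[1:]):
        if y <= x:
            continue
        cover = [covering(bi, x, y) for bi in range(len(per_batch))]
        if any(c is None for c in cover):
            continue
        placements: dict[str, tuple[int, bool]] = {ref_id: (x, False)}
        flen = y - x
        for bi, m in enumerate(cover):
            d = x - m.start(ref_id)
            for gid, (s, rev) in m.placements.items():
                if gid == ref_id:
                    continue
                if not rev:
                    placements[gid] = (s + d, False)
                else:
                    placements[gid] = (s + (m.length - d - flen), True)
        frag = MultiMUM(length=flen, placements=placements)
        # verify all-genome uniqueness of the fragment substring
        sub = reference.concat[x:y]
        if all(
            count_occurrences(g.concat, sub, both_strands=True) == 1
            for g in all_genomes
        ):
            fragments.append(frag)
        else:
            dropped += 1
    if dropped:
        log.info("partition merge dropped %d non-unique fragments", dropped)

    # merge fragments contiguous in every genome
    fragments.sort(key=lambda m: m.start(ref_id))
    merged: list[MultiMUM] = []
    for frag in fragments:
        if merged:
            prev = merged[-1]
            if prev.end(ref_id) == frag.start(ref_id) and all(
                gid in prev.placements
                and prev.placements[gid][1] == rev
                and (
                    (not rev and s == prev.placements[gid][0] + prev.length)
                    or (rev and s + frag.length == prev.placements[gid][0])
                )
                for gid, (s, rev) in frag.placements.items()
            ):
                merged[-1] = MultiMUM(
                    length=prev.length + frag.length,
                    placements={
                        gid: (min(s, frag.placements[gid][0]) if rev else s, rev)
                        for gid, (s, rev) in prev.placements.items()
                    },
                )
                continue
        merged.append(frag)
    return merged
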