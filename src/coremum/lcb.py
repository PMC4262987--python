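"""Locally collinear blocks: chaining anchors and weight filtering.

An LCB is a maximal run of multi-MUM anchors whose order and relative
orientation are consistent in every genome; it is the unit within which
the gapped core alignment is computed.  Chains break where order or
orientation becomes inconsistent in any genome or where the inter-anchor
distance in any genome exceeds ``max_gap``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import NoCoreAlignmentError
from .multimum import MultiMUM, pair_gaps

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 10_000


@dataclass
class LCB:
    """An ordered run of collinear anchors."""

    id: int
    anchors: list[MultiMUM]
    kept: bool = True

    @property
    def weight(self) -> int:
        return sum(a.length for a in self.anchors)

    def genome_ids(self) -> list[str]:
        return list(self.anchors[0].placements.keys())

    def orientation(self, gid: str) -> bool:
        """True when this genome runs reverse through the block."""
        return self.anchors[0].placements[gid][1]

    def extent(self, gid: str) -> tuple[int, int]:
        """Forward-strand [start, end) of the block in this genome."""
        starts = [a.start(gid) for a in self.anchors]
        ends = [a.end(gid) for a in self.anchors]
        return min(starts), max(ends)

    def ref_extent(self) -> tuple[int, int]:
        ref_id = self.genome_ids()[0]
        return self.extent(ref_id)


DEFAULT_MAX_DIAG_DIFF = 100


def chain_lcbs(
    anchors: list[MultiMUM],
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_diff: int | None = DEFAULT_MAX_DIAG_DIFF,
) -> list[LCB]:
    """Partition anchors into LCBs by greedy extension in reference order."""
    if not anchors:
        return []
    gids = list(anchors[0].placements.keys())
    ref_id = gids[0]
    ordered = sorted(anchors, key=lambda m: m.start(ref_id))
    lcbs: list[LCB] = []
    current: list[MultiMUM] = [ordered[0]]
    for nxt in ordered[1:]:
        if pair_gaps(current[-1], nxt, gids, max_gap, max_diag_diff) is not None:
            current.append(nxt)
        else:
            lcbs.append(LCB(id=len(lcbs), anchors=current))
            current = [nxt]
    lcbs.append(LCB(id=len(lcbs), anchors=current))
    log.info("chained %d anchors into %d LCBs", len(ordered), len(lcbs))
    return lcbs


def filter_lcbs(
    lcbs: list[LCB], min_weight: int
) -> tuple[list[LCB], list[LCB]]:
    """Split blocks into (kept, dropped) by summed anchor length.

    Dropped blocks are not discarded: their columns are flagged rather
    than silently lost.
    """
    kept, dropped = [], []
    for lcb in lcbs:
        if lcb.weight >= min_weight:
            lcb.kept = True
            kept.append(lcb)
        else:
            lcb.kept = False
            dropped.append(lcb)
    if lcbs and not kept:
        raise NoCoreAlignmentError(
            "no core alignment: every LCB fell below the weight threshold"
        )
    log.info(
        "LCB weight filter (min %d): kept %d, dropped %d",
        min_weight, len(kept), len(dropped),
    )
    return kept, dropped
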