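"""MUMi distance and genome recruitment.

The MUMi distance between two genomes is 1 - L_mum / L_av, where L_mum
is the summed length of non-overlapping MUMs (both strands) and L_av the
average of the two genome lengths.  Identical genomes have distance 0;
genomes sharing no MUM have distance 1.  Only candidates within the
recruitment threshold of the reference enter the full alignment; the
threshold is deliberately permissive so that genomes at the ~97% ANI
boundary of a species are admitted, and can be overridden entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import NoGenomesRecruitedError
from .match_core import scan_multimums
from .sequence_io import Genome

log = logging.getLogger(__name__)

DEFAULT_MUMI_MIN_LEN = 19
DEFAULT_MUMI_THRESHOLD = 0.3


def _trim_amounts(s: int, e: int, kept: list[tuple[int, int]]) -> tuple[int, int] | None:
    """Left/right trims needed for [s,e) to avoid the kept intervals; the
    longest free stretch wins (leftmost on ties).  None when swallowed."""
    free = []
    cur = s
    for ks, ke in kept:
        if ke <= s or ks >= e:
            continue
        if ks > cur:
            free.append((cur, ks))
        cur = max(cur, ke)
    if cur < e:
        free.append((cur, e))
    if not free:
        return None
    fs, fe = max(free, key=lambda iv: (iv[1] - iv[0], -iv[0]))
    return fs - s, e - fe


def mumi_distance(a: Genome, b: Genome, min_len: int = DEFAULT_MUMI_MIN_LEN) -> float:
    """Symmetric MUMi distance in [0, 1]."""
    matches = scan_multimums([a.concat, b.concat], min_len)
    # greedy longest-first trimming to non-overlapping coverage on BOTH
    # genomes; the sort key is invariant under swapping a and b
    order = sorted(
        matches,
        key=lambda m: (
            -m.length,
            min(m.placements[0][0], m.placements[1][0]),
            max(m.placements[0][0], m.placements[1][0]),
        ),
    )
    kept_a: list[tuple[int, int]] = []
    kept_b: list[tuple[int, int]] = []
    l_mum = 0
    for m in order:
        a_s, _ = m.placements[0]
        b_s, rev = m.placements[1]
        length = m.length
        while length > 0:
            ta = _trim_amounts(a_s, a_s + length, sorted(kept_a))
            tb = _trim_amounts(b_s, b_s + length, sorted(kept_b))
            if ta is None or tb is None:
                length = 0
                break
            dl_a, dr_a = ta
            dl_b, dr_b = tb
            if not rev:
                dl = max(dl_a, dl_b)
                dr = max(dr_a, dr_b)
            else:
                # on a reverse match, b's left trim cuts a's right end
                dl = max(dl_a, dr_b)
                dr = max(dr_a, dl_b)
            if dl == 0 and dr == 0:
                break
            length -= dl + dr
            if length <= 0:
                length = 0
                break
            a_s += dl
            b_s += dl if not rev else dr
        if length <= 0:
            continue
        kept_a.append((a_s, a_s + length))
        kept_b.append((b_s, b_s + length))
        l_mum += length
    l_av = (a.nt_length + b.nt_length) / 2.0
    if l_av == 0:
        raise ValueError("empty genomes")
    return min(1.0, max(0.0, 1.0 - l_mum / l_av))


@dataclass
class RecruitmentReport:
    """Per-candidate MUMi distances and recruitment decisions."""

    threshold: float
    entries: list[tuple[str, float, bool]] = field(default_factory=list)
    # (genome id, mumi, recruited)

    def recruited_ids(self) -> list[str]:
        return [gid for gid, _, rec in self.entries if rec]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("genome\tmumi\trecruited\n")
            for gid, d, rec in self.entries:
                out.write(f"{gid}\t{d:.6f}\t{str(rec).lower()}\n")


def recruit(
    reference: Genome,
    candidates: list[Genome],
    threshold: float = DEFAULT_MUMI_THRESHOLD,
    force_all: bool = False,
    min_len: int = DEFAULT_MUMI_MIN_LEN,
) -> RecruitmentReport:
    """Recruit candidates within the MUMi threshold of the reference.

    With force_all every candidate is recruited, but distances are still
    computed and reported.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    report = RecruitmentReport(threshold=threshold)
    for g in candidates:
        d = mumi_distance(reference, g, min_len)
        rec = force_all or d <= threshold
        if not rec:
            log.warning("excluding %s: MUMi %.4f > threshold %.4f", g.id, d, threshold)
        report.entries.append((g.id, d, rec))
    if not any(rec for _, _, rec in report.entries):
        raise NoGenomesRecruitedError(
            "no genomes recruited; consider raising the MUMi threshold or "
            "forcing inclusion"
        )
    return report
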