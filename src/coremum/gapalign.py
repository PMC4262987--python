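"""Alignment of the short unanchored gaps between consecutive anchors.

Gaps inside an LCB are typically a handful of bases (a single SNP column
in the degenerate case), so a deterministic progressive scheme is used:
pairwise global alignment with affine gaps (match +5, mismatch -4, gap
open -12, gap extend -1; a length-k gap costs open + (k-1)*extend),
guide order by decreasing sequence length with ties broken by genome id.
Identical gap sequences are collapsed before alignment and re-expanded
afterwards, so the result is independent of how many genomes carry each
distinct sequence.  Pairwise steps run through Biopython's
PairwiseAligner; sequences join an existing profile through a Gotoh
profile-to-sequence step with mean-of-pairs column scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InternalConsistencyError
from .lcb import LCB
from .multimum import MultiMUM
from .sequence_io import SEP, Genome, revcomp

MATCH = 5
MISMATCH = -4
GAP_OPEN = -12
GAP_EXTEND = -1
#: score of a residue against a gap character inside a profile column
PROFILE_GAP_SCORE = GAP_EXTEND

_ALPHABET = "ACGTN"


def _make_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            # N never matches anything, including another N
            matrix[x, y] = MATCH if (x == y and x != "N") else MISMATCH
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_PAIR_ALIGNER = _make_aligner()


def pairwise_align(s1: str, s2: str) -> tuple[str, str, float]:
    """Deterministic global affine alignment of two sequences."""
    if not s1 and not s2:
        return "", "", 0.0
    if not s1:
        return "-" * len(s2), s2, GAP_OPEN + (len(s2) - 1) * GAP_EXTEND
    if not s2:
        return s1, "-" * len(s1), GAP_OPEN + (len(s1) - 1) * GAP_EXTEND
    aln = _PAIR_ALIGNER.align(s1, s2)[0]
    return str(aln[0]), str(aln[1]), aln.score


def pairwise_score(s1: str, s2: str) -> float:
    """Optimal global affine alignment score."""
    return pairwise_align(s1, s2)[2]


def _subst(c1: str, c2: str) -> int:
    if c1 == "-" or c2 == "-":
        return PROFILE_GAP_SCORE
    return MATCH if (c1 == c2 and c1 != "N") else MISMATCH


def profile_align(rows: list[str], seq: str) -> tuple[list[str], str]:
    """Align one sequence to an existing profile (Gotoh, deterministic).

    Returns the rows with any new all-gap columns inserted, plus the
    aligned sequence row.  Ties in the traceback prefer substitution,
    then a gap column in the profile, then a gap in the sequence.
    """
    ncols = len(rows[0])
    nrows = len(rows)
    m = len(seq)
    if m == 0:
        return list(rows), "-" * ncols
    if ncols == 0:
        return ["-" * m for _ in rows], seq

    # mean-of-pairs column scores, precomputed per column and base
    alpha = "ACGTN"
    col_tab: list[dict[str, float]] = []
    for j in range(ncols):
        col_chars = [r[j] for r in rows]
        col_tab.append(
            {c: sum(_subst(c, x) for x in col_chars) / nrows for c in alpha}
        )

    def col_score(j: int, c: str) -> float:
        return col_tab[j][c]

    NEG = float("-inf")
    # DP over i (seq prefix) x j (profile prefix); states M, X (seq char
    # against new gap column), Y (profile column against gap in seq)
    M = [[NEG] * (ncols + 1) for _ in range(m + 1)]
    X = [[NEG] * (ncols + 1) for _ in range(m + 1)]
    Y = [[NEG] * (ncols + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, ncols + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, m + 1):
        ci = seq[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, ncols + 1):
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + col_score(j - 1, ci)
            Xi[j] = max(Mp[j] + GAP_OPEN, Xp[j] + GAP_EXTEND, Yp[j] + GAP_OPEN)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND,
                        Xi[j - 1] + GAP_OPEN)

    # traceback with fixed preference M > X > Y
    ops: list[str] = []
    i, j = m, ncols
    state = "M"
    best = max(M[i][j], X[i][j], Y[i][j])
    for name, val in (("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])):
        if val == best:
            state = name
            break
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            i, j = i - 1, j - 1
            for name, val in (("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])):
                if abs(val - prev) < eps:
                    state = name
                    break
        elif state == "X":
            ops.append("X")
            cur = X[i][j]
            if abs(M[i - 1][j] + GAP_OPEN - cur) < eps:
                state = "M"
            elif abs(X[i - 1][j] + GAP_EXTEND - cur) < eps:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            ops.append("Y")
            cur = Y[i][j]
            if abs(M[i][j - 1] + GAP_OPEN - cur) < eps:
                state = "M"
            elif abs(Y[i][j - 1] + GAP_EXTEND - cur) < eps:
                state = "Y"
            else:
                state = "X"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    ops.reverse()

    new_rows = ["" for _ in rows]
    out_seq = []
    i = j = 0
    for op in ops:
        if op == "M":
            for r, row in enumerate(rows):
                new_rows[r] += row[j]
            out_seq.append(seq[i])
            i += 1
            j += 1
        elif op == "X":
            for r in range(nrows):
                new_rows[r] += "-"
            out_seq.append(seq[i])
            i += 1
        else:
            for r, row in enumerate(rows):
                new_rows[r] += row[j]
            out_seq.append("-")
            j += 1
    return new_rows, "".join(out_seq)


def _representative_join(rows: list[str], seq: str) -> tuple[list[str], str]:
    """Join a sequence to a profile by pairwise alignment against the
    first (guide) row; columns where the guide gains a gap are inserted
    into every row."""
    guide = rows[0]
    core = guide.replace("-", "")
    a_core, a_seq, _ = pairwise_align(core, seq)
    new_rows = ["" for _ in rows]
    out_seq = []
    j = 0  # column in the existing profile
    for cg, cs in zip(a_core, a_seq):
        if cg == "-":
            for r in range(len(rows)):
                new_rows[r] += "-"
            out_seq.append(cs)
            continue
        # consume profile columns until the guide shows its next residue
        while guide[j] == "-":
            for r, row in enumerate(rows):
                new_rows[r] += row[j]
            out_seq.append("-")
            j += 1
        for r, row in enumerate(rows):
            new_rows[r] += row[j]
        out_seq.append(cs)
        j += 1
    while j < len(guide):
        for r, row in enumerate(rows):
            new_rows[r] += row[j]
        out_seq.append("-")
        j += 1
    return new_rows, "".join(out_seq)


@dataclass
class GapBlock:
    """One aligned inter-anchor gap: equal-length rows per genome."""

    rows: dict[str, str]

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))


def align_gap(gaps: dict[str, str], max_gap_len: int = 10_000) -> GapBlock:
    """Multiple alignment of per-genome gap sequences.

    Degenerate cases short-circuit: all gaps empty, all identical, or a
    single non-empty gap.  Otherwise identical sequences are collapsed
    and aligned progressively, longest first (ties by smallest carrier
    genome id).
    """
    for gid, s in gaps.items():
        if len(s) > max_gap_len:
            raise ValueError(
                f"gap of {len(s)} bases in {gid} exceeds max_gap_len {max_gap_len}"
            )
    distinct = sorted(set(gaps.values()))
    if distinct == [""]:
        return GapBlock(rows={gid: "" for gid in gaps})
    if len(distinct) == 1:
        return GapBlock(rows=dict(gaps))
    nonempty = [s for s in distinct if s]
    if len(nonempty) == 1:
        s = nonempty[0]
        return GapBlock(
            rows={gid: (g if g else "-" * len(s)) for gid, g in gaps.items()}
        )

    carrier = {s: min(gid for gid, g in gaps.items() if g == s) for s in distinct}
    order = sorted(distinct, key=lambda s: (-len(s), carrier[s]))
    aligned = [order[0]]
    for s in order[1:]:
        if len(aligned) == 1:
            a, b, _ = pairwise_align(aligned[0], s)
            aligned = [a, b]
        elif len(s) * len(aligned[0]) > 500_000:
            # oversized join: align against the guide row and propagate
            # its gap columns (profile DP would be quadratic in python)
            new_rows, out = _representative_join(aligned, s)
            aligned = new_rows + [out]
        else:
            new_rows, out = profile_align(aligned, s)
            aligned = new_rows + [out]
    by_seq = {s: aligned[k] for k, s in enumerate(order)}
    return GapBlock(rows={gid: by_seq[g] for gid, g in gaps.items()})


# ---------------------------------------------------------------------------
# assembling the core alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedLCB:
    """An LCB with its gapped alignment: anchors alternate with gap blocks."""

    lcb: LCB
    segments: list[tuple[str, object]]  # ("anchor", str) | ("gap", GapBlock)

    @property
    def ncols(self) -> int:
        total = 0
        for kind, payload in self.segments:
            total += len(payload) if kind == "anchor" else payload.width
        return total

    def row(self, gid: str) -> str:
        parts = []
        for kind, payload in self.segments:
            parts.append(payload if kind == "anchor" else payload.rows[gid])
        return "".join(parts)


@dataclass
class CoreAlignment:
    """The full gapped core-genome alignment, one AlignedLCB per block."""

    genome_ids: list[str]
    lcbs: list[AlignedLCB]

    @property
    def core_columns(self) -> int:
        return sum(b.ncols for b in self.lcbs if b.lcb.kept)

    def kept_lcbs(self) -> list[AlignedLCB]:
        return [b for b in self.lcbs if b.lcb.kept]


def extract_gap_sequences(
    lcb: LCB, prev: MultiMUM, nxt: MultiMUM, genomes_by_id: dict[str, Genome]
) -> dict[str, str]:
    """Per-genome unanchored sequence between two consecutive anchors,
    oriented to the alignment (reference) direction.  Contig separators
    falling inside a gap are replaced by N."""
    gaps = {}
    for gid in lcb.genome_ids():
        genome = genomes_by_id[gid]
        if not lcb.orientation(gid):
            lo, hi = prev.end(gid), nxt.start(gid)
            seq = genome.concat[lo:hi]
        else:
            lo, hi = nxt.end(gid), prev.start(gid)
            seq = revcomp(genome.concat[lo:hi])
        gaps[gid] = seq.replace(SEP, "N")
    return gaps


def align_lcb(
    lcb: LCB,
    genomes_by_id: dict[str, Genome],
    max_gap_len: int = 10_000,
) -> AlignedLCB:
    """Align all inter-anchor gaps of one LCB."""
    ref_id = lcb.genome_ids()[0]
    ref = genomes_by_id[ref_id]
    segments: list[tuple[str, object]] = []
    for k, anchor in enumerate(lcb.anchors):
        if k > 0:
            gaps = extract_gap_sequences(lcb, lcb.anchors[k - 1], anchor, genomes_by_id)
            if any(gaps.values()):
                segments.append(("gap", align_gap(gaps, max_gap_len)))
        text = ref.concat[anchor.start(ref_id):anchor.end(ref_id)]
        segments.append(("anchor", text))
    return AlignedLCB(lcb=lcb, segments=segments)


def assemble_core_alignment(
    aligned: list[AlignedLCB],
    genomes_by_id: dict[str, Genome],
) -> CoreAlignment:
    """Validate reconstruction and assemble the core alignment.

    Degapping every row of every block must reproduce the genome's
    substring over the block extent exactly (reverse-complemented for
    reverse-orientation genomes); any mismatch is a fatal internal error.
    """
    if not aligned:
        raise InternalConsistencyError("no aligned LCBs")
    genome_ids = aligned[0].lcb.genome_ids()
    for block in aligned:
        for gid in genome_ids:
            row = block.row(gid).replace("-", "")
            lo, hi = block.lcb.extent(gid)
            expected = genomes_by_id[gid].concat[lo:hi]
            if block.lcb.orientation(gid):
                expected = revcomp(expected)
            expected = expected.replace(SEP, "N")
            if row != expected:
                raise InternalConsistencyError(
                    f"LCB {block.lcb.id}: degapped row of {gid} does not "
                    f"reproduce the genome substring"
                )
    return CoreAlignment(genome_ids=genome_ids, lcbs=aligned)
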