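"""Scoring SNP calls, per-branch errors and breakpoint recovery against
simulated truth.

A call is one (ancestor position, genome, allele) triple derived from
the core SNP matrix: the genome's allele at a called column, mapped from
reference coordinates to ancestor coordinates (complemented when the
reference segment is inverted relative to the ancestor) and differing
from the ancestral base.  Truth triples at positions not covered by the
core alignment count as false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .simulate import SimTruth
from .variants import SnpMatrix

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    per_genome: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0


def _call_triples(
    calls: SnpMatrix, truth: SimTruth, reference: str
) -> set[tuple[int, str, str]]:
    triples: set[tuple[int, str, str]] = set()
    for v in calls.columns:
        if v.ref_pos is None:
            continue
        p, strand = truth.leaf_to_anc(reference, v.ref_pos)
        anc_base = truth.ancestor[p]
        for gid, allele in zip(calls.genome_ids, v.alleles):
            a = _COMP[allele] if strand == "-" else allele
            if a != anc_base:
                triples.add((p, gid, a))
    return triples


def _truth_triples(truth: SimTruth) -> set[tuple[int, str, str]]:
    return {
        (pos, gid, allele)
        for gid, snps in truth.snps.items()
        for pos, allele in snps.items()
    }


def evaluate_snps(
    calls: SnpMatrix, truth: SimTruth, reference: str
) -> EvaluationResult:
    """TP/FP/FN per (ancestor position, genome, allele) triple."""
    call_set = _call_triples(calls, truth, reference)
    truth_set = _truth_triples(truth)
    tp_set = call_set & truth_set
    fp_set = call_set - truth_set
    fn_set = truth_set - call_set
    per_genome: dict[str, tuple[int, int, int]] = {}
    for gid in calls.genome_ids:
        per_genome[gid] = (
            sum(1 for t in tp_set if t[1] == gid),
            sum(1 for t in fp_set if t[1] == gid),
            sum(1 for t in fn_set if t[1] == gid),
        )
    return EvaluationResult(
        tp=len(tp_set), fp=len(fp_set), fn=len(fn_set), per_genome=per_genome
    )


# ---------------------------------------------------------------------------
# per-branch errors
# ---------------------------------------------------------------------------

@dataclass
class BranchErrorReport:
    """Per-split SNP counts and branch-length errors.

    Splits are canonicalized as the frozenset of genomes carrying the
    derived (non-ancestral) allele; splits matching no edge of the
    estimated tree are counted as unassignable."""

    per_branch: dict[frozenset, dict[str, float]]
    unassignable_called: int
    unassignable_true: int


def _tree_splits(tree: dendropy.Tree, taxa: list[str]) -> dict[frozenset, float]:
    """Map each edge to its leaf-set split (both sides canonical) and
    branch length."""
    full = frozenset(taxa)
    splits: dict[frozenset, float] = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.length is None:
            continue
        below = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        if not below or below == full:
            continue
        for side in (below, full - below):
            prev = splits.get(side, 0.0)
            splits[side] = max(prev, float(edge.length))
    return splits


def branch_errors(
    estimated: dendropy.Tree,
    calls: SnpMatrix,
    truth: SimTruth,
    reference: str,
) -> BranchErrorReport:
    """Assign called and true SNPs to the splits they support and report
    per-branch counts plus length errors (estimated - true, in SNP
    units: estimated branch length x retained SNP columns)."""
    taxa = list(calls.genome_ids)
    splits = _tree_splits(estimated, taxa)
    n_cols = max(1, len(calls))

    def split_of(carriers: frozenset) -> frozenset | None:
        if carriers in splits:
            return carriers
        other = frozenset(taxa) - carriers
        if other in splits:
            return other
        return None

    called_counts: dict[frozenset, int] = {}
    unassignable_called = 0
    # group call triples by (position, allele)
    grouped: dict[tuple[int, str], set[str]] = {}
    for p, gid, a in _call_triples(calls, truth, reference):
        grouped.setdefault((p, a), set()).add(gid)
    for (_p, _a), carriers in grouped.items():
        s = split_of(frozenset(carriers))
        if s is None:
            unassignable_called += 1
        else:
            called_counts[s] = called_counts.get(s, 0) + 1

    true_counts: dict[frozenset, int] = {}
    unassignable_true = 0
    grouped_t: dict[tuple[int, str], set[str]] = {}
    for p, gid, a in _truth_triples(truth):
        grouped_t.setdefault((p, a), set()).add(gid)
    for (_p, _a), carriers in grouped_t.items():
        s = split_of(frozenset(carriers))
        if s is None:
            unassignable_true += 1
        else:
            true_counts[s] = true_counts.get(s, 0) + 1

    report: dict[frozenset, dict[str, float]] = {}
    for s, length in splits.items():
        called = called_counts.get(s, 0)
        true = true_counts.get(s, 0)
        report[s] = {
            "called": called,
            "true": true,
            "fp": max(0, called - true),
            "fn": max(0, true - called),
            "length_snps": length * n_cols,
            "length_error": length * n_cols - true,
        }
    return BranchErrorReport(
        per_branch=report,
        unassignable_called=unassignable_called,
        unassignable_true=unassignable_true,
    )


# ---------------------------------------------------------------------------
# breakpoint recovery
# ---------------------------------------------------------------------------

def breakpoint_recovery(
    lcb_boundaries: list[int],
    truth: SimTruth,
    reference: str,
    tolerance: int = 50,
) -> float | None:
    """Fraction of planted breakpoints within +/- tolerance of an LCB
    boundary (boundaries given in reference coordinates and projected to
    the ancestor).  None when the truth set has no breakpoints."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    all_bps = truth.all_breakpoints()
    if not all_bps:
        return None
    ref_len = sum(b - a for _, a, b, _s in truth.segmap[reference])
    projected = []
    for b in lcb_boundaries:
        pos = min(max(b, 0), ref_len - 1)
        p, _ = truth.leaf_to_anc(reference, pos)
        projected.append(p)
    projected.sort()

    import bisect

    recovered = 0
    for _gid, bp in all_bps:
        i = bisect.bisect_left(projected, bp - tolerance)
        if i < len(projected) and projected[i] <= bp + tolerance:
            recovered += 1
    return recovered / len(all_bps)
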