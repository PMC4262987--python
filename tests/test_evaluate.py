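"""SNP-call scoring, branch assignment and breakpoint recovery."""

import pytest

from coremum.evaluate import (
    EvaluationResult,
    branch_errors,
    breakpoint_recovery,
    evaluate_snps,
)
from coremum.phylogeny import read_newick
from coremum.simulate import SimConfig, SimTruth, simulate_evolution
from coremum.variants import SnpMatrix, VariantColumn


def _truth_for(ancestor: str, snps: dict) -> SimTruth:
    gids = sorted(snps)
    L = len(ancestor)
    return SimTruth(
        ancestor=ancestor,
        tree_newick="",
        branch_events={},
        snps=snps,
        breakpoints={g: [] for g in gids},
        rearrangements={},
        segmap={g: [(0, 0, L, "+")] for g in gids},
    )


def _calls(gids, columns):
    cols = [
        VariantColumn(
            lcb_id=0, col=i, ref_pos=pos, alleles=alleles,
            positions=tuple([pos] * len(gids)),
        )
        for i, (pos, alleles) in enumerate(columns)
    ]
    return SnpMatrix(genome_ids=gids, columns=cols)


def test_formulas():
    r = EvaluationResult(tp=90, fp=0, fn=10)
    assert r.tpr == pytest.approx(0.9)
    assert r.fdr == 0.0


def test_calls_equal_truth_perfect_scores():
    anc = "A" * 50
    truth = _truth_for(anc, {"r": {}, "x": {10: "G"}, "y": {10: "G", 20: "C"}})
    calls = _calls(["r", "x", "y"], [(10, "AGG"), (20, "AAC")])
    ev = evaluate_snps(calls, truth, "r")
    assert (ev.tp, ev.fp, ev.fn) == (3, 0, 0)
    assert ev.tpr == 1.0 and ev.fdr == 0.0


def test_perturbed_calls_raise_fp_exactly():
    anc = "A" * 100
    snps = {"r": {}, "x": {i: "G" for i in range(0, 50, 10)}}
    truth = _truth_for(anc, snps)
    cols = [(i, "AG") for i in range(0, 50, 10)]
    # perturb 2 calls to a wrong allele: each becomes FP and leaves an FN
    cols[0] = (0, "AC")
    cols[1] = (10, "AT")
    ev = evaluate_snps(_calls(["r", "x"], cols), truth, "r")
    assert ev.fp == 2
    assert ev.fn == 2
    assert ev.tp == 3


def test_uncovered_truth_counts_as_fn():
    anc = "A" * 40
    truth = _truth_for(anc, {"r": {}, "x": {5: "T", 25: "C"}})
    ev = evaluate_snps(_calls(["r", "x"], [(5, "AT")]), truth, "r")
    assert (ev.tp, ev.fp, ev.fn) == (1, 0, 1)


def test_conservation_on_simulated_run(run8):
    _, truth, result = run8
    ev = evaluate_snps(result.snps, truth, result.reference.id)
    truth_total = sum(len(s) for s in truth.snps.values())
    assert ev.tp + ev.fn == truth_total
    per = [sum(x) for x in zip(*ev.per_genome.values())]
    assert per[0] == ev.tp and per[1] == ev.fp and per[2] == ev.fn


def test_breakpoint_recovery_bounds():
    anc = "A" * 1000
    truth = _truth_for(anc, {"r": {}, "x": {}})
    truth.breakpoints["x"] = [100, 500]
    assert breakpoint_recovery([100, 500], truth, "r", 0) == 1.0
    assert breakpoint_recovery([], truth, "r", 50) == 0.0
    assert breakpoint_recovery([160], truth, "r", 50) == 0.0
    assert breakpoint_recovery([149], truth, "r", 50) == 0.5
    truth.breakpoints["x"] = []
    assert breakpoint_recovery([100], truth, "r", 50) is None


def test_branch_errors_zero_when_calls_equal_truth():
    anc = "A" * 60
    truth = _truth_for(anc, {
        "a": {10: "G", 30: "C"}, "b": {10: "G", 30: "C"},
        "c": {40: "T"}, "d": {},
    })
    calls = _calls(
        ["a", "b", "c", "d"],
        [(10, "GGAA"), (30, "CCAA"), (40, "AATA")],
    )
    tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
    report = branch_errors(tree, calls, truth, "a")
    assert report.unassignable_called == 0
    for stats in report.per_branch.values():
        assert stats["fp"] == 0 and stats["fn"] == 0


def test_branch_errors_fabricated_singleton_is_fp():
    anc = "A" * 60
    truth = _truth_for(anc, {"a": {}, "b": {}, "c": {}, "d": {}})
    calls = _calls(["a", "b", "c", "d"], [(10, "GAAA")])  # fake SNP on a
    tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
    report = branch_errors(tree, calls, truth, "a")
    pendant_a = frozenset({"a"})
    assert report.per_branch[pendant_a]["fp"] == 1
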