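"""Simulator truth bookkeeping and calibration."""

import numpy as np
import pytest

from coremum.sequence_io import revcomp
from coremum.simulate import (
    SimConfig,
    load_truth,
    simulate_evolution,
    write_dataset,
)


def test_seed_determinism():
    c = SimConfig(length=8000, leaves=4, rate=1e-3, n_rearrangements=2, seed=9)
    g1, t1 = simulate_evolution(c)
    g2, t2 = simulate_evolution(SimConfig(**{**c.__dict__}))
    assert [g.contigs for g in g1] == [g.contigs for g in g2]
    assert t1.snps == t2.snps and t1.breakpoints == t2.breakpoints


def test_rate_zero_no_rearrangements_identity():
    genomes, truth = simulate_evolution(SimConfig(
        length=5000, leaves=4, rate=0.0, n_rearrangements=0, seed=3,
    ))
    assert all(g.contigs[0][1] == truth.ancestor for g in genomes)
    assert all(not s for s in truth.snps.values())


def test_invalid_rate_rejected():
    with pytest.raises(ValueError):
        SimConfig(rate=0.8)


def test_substitution_count_within_3_sigma():
    L, rate, leaves = 100_000, 1e-3, 32
    _, truth = simulate_evolution(SimConfig(
        length=L, leaves=leaves, rate=rate, n_rearrangements=0, seed=12,
    ))
    total = sum(len(ev) for ev in truth.branch_events.values())
    branches = len(truth.branch_events)
    assert branches == 62  # balanced 32-leaf tree
    mean = branches * L * rate
    sigma = np.sqrt(mean)
    assert abs(total - mean) < 3 * sigma


def test_transition_transversion_ratio():
    _, truth = simulate_evolution(SimConfig(
        length=200_000, leaves=2, rate=5e-3, tstv=4.0,
        n_rearrangements=0, seed=3,
    ))
    ts = tv = 0
    for events in truth.branch_events.values():
        for _pos, f, t in events:
            if {f, t} in ({"A", "G"}, {"C", "T"}):
                ts += 1
            else:
                tv += 1
    ratio = ts / tv
    assert abs(ratio - 4.0) < 0.5


def test_leaf_reconstruction_from_truth():
    genomes, truth = simulate_evolution(SimConfig(
        length=20_000, leaves=8, rate=1e-3, n_rearrangements=3, seed=11,
    ))
    for g in genomes:
        evolved = list(truth.ancestor)
        for pos, allele in truth.snps[g.id].items():
            evolved[pos] = allele
        evolved = "".join(evolved)
        rebuilt = "".join(
            evolved[a:b] if s == "+" else revcomp(evolved[a:b])
            for _, a, b, s in truth.segmap[g.id]
        )
        assert rebuilt == g.contigs[0][1]


def test_leaf_to_anc_round_trip():
    genomes, truth = simulate_evolution(SimConfig(
        length=10_000, leaves=4, rate=1e-3, n_rearrangements=4, seed=21,
    ))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for g in genomes:
        seq = g.contigs[0][1]
        evolved = list(truth.ancestor)
        for pos, allele in truth.snps[g.id].items():
            evolved[pos] = allele
        for pos in range(0, len(seq), 503):
            p, strand = truth.leaf_to_anc(g.id, pos)
            expect = evolved[p] if strand == "+" else comp[evolved[p]]
            assert seq[pos] == expect


def test_rearrangement_sizes_near_mean():
    _, truth = simulate_evolution(SimConfig(
        length=50_000, leaves=4, rate=0.0, n_rearrangements=8,
        rearrangement_size=1000, seed=33,
    ))
    sizes = [
        e - s for ops in truth.rearrangements.values()
        for _kind, s, e, _x in ops
    ]
    assert sizes
    assert 600 < np.mean(sizes) < 1400


def test_planted_repeats_duplicate_sequence():
    _, truth = simulate_evolution(SimConfig(
        length=10_000, leaves=2, rate=0.0, n_rearrangements=0,
        planted_repeats=[(400, 2)], seed=5,
    ))
    # the duplicated segment makes some 100-mer occur twice
    anc = truth.ancestor
    seen = set()
    found = False
    for i in range(len(anc) - 100 + 1):
        km = anc[i:i + 100]
        if km in seen:
            found = True
            break
        seen.add(km)
    assert found


def test_dataset_round_trip(tmp_path):
    genomes, truth = simulate_evolution(SimConfig(
        length=6000, leaves=4, rate=1e-3, n_rearrangements=2, seed=8,
    ))
    write_dataset(tmp_path, genomes, truth)
    back = load_truth(tmp_path)
    assert back.ancestor == truth.ancestor
    assert back.snps == truth.snps
    assert back.breakpoints == truth.breakpoints
    assert back.segmap == truth.segmap
    assert back.tree_newick.strip() == truth.tree_newick.strip()
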