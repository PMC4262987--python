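"""Variant extraction and the five-criterion filter stack."""

import random
import re

import numpy as np
import pytest

from conftest import mutate_seq, random_seq, toy_genome
from coremum.gapalign import align_lcb, assemble_core_alignment
from coremum.lcb import chain_lcbs
from coremum.multimum import find_multimums
from coremum.sequence_io import Genome, revcomp
from coremum.variants import (
    FLAG_ALN,
    FLAG_LCB,
    FLAG_QUAL,
    FLAG_REC,
    FLAG_REP,
    VariantColumn,
    core_snps,
    extract_columns,
    flag_alignment_quality,
    flag_lcb_size,
    flag_repetitive,
    phi_recombination,
    repetitive_mask,
)


def _core_from(seqs: dict[str, str], min_len=12):
    gs = [toy_genome(gid, s) for gid, s in sorted(seqs.items())]
    anchors = find_multimums(gs[1:], gs[0], min_len=min_len)
    gby = {g.id: g for g in gs}
    aligned = [align_lcb(b, gby) for b in chain_lcbs(anchors)]
    return assemble_core_alignment(aligned, gby)


def _col(col, alleles, ref_pos=None, lcb_id=0):
    return VariantColumn(
        lcb_id=lcb_id, col=col, ref_pos=ref_pos, alleles=alleles,
        positions=tuple([None] * len(alleles)),
    )


def test_single_substitution_yields_one_column(rng):
    seq = random_seq(rng, 400)
    var = seq[:200] + ("A" if seq[200] != "A" else "G") + seq[201:]
    core = _core_from({"a": seq, "b": var})
    cols = extract_columns(core)
    assert len(cols) == 1
    assert not cols[0].is_indel
    assert cols[0].ref_pos == 200


def test_identical_genomes_no_columns(rng):
    seq = random_seq(rng, 300)
    core = _core_from({"a": seq, "b": seq})
    assert extract_columns(core) == []


def test_extraction_count_tracks_planted_snps(rng):
    local = random.Random(99)
    seq = random_seq(local, 5000)
    variants = {"a": seq}
    planted = set()
    for gid in ("b", "c", "d"):
        s = list(seq)
        for _ in range(25):
            p = local.randrange(len(seq))
            s[p] = local.choice([c for c in "ACGT" if c != seq[p]])
            planted.add(p)
        variants[gid] = "".join(s)
    core = _core_from(variants)
    cols = extract_columns(core)
    assert abs(len(cols) - len(planted)) <= 0.05 * len(planted) + 2


def test_rep_flag_inside_duplication(rng):
    local = random.Random(42)
    dup = random_seq(local, 500)
    ref = toy_genome("r", random_seq(local, 300) + dup
                     + random_seq(local, 300) + dup + random_seq(local, 200))
    inside = _col(0, "AC", ref_pos=350)
    outside = _col(1, "AG", ref_pos=100)
    flag_repetitive([inside, outside], ref, repeat_kmer=21)
    assert FLAG_REP in inside.flags
    assert FLAG_REP not in outside.flags


def test_repetitive_mask_matches_regex_oracle(rng):
    local = random.Random(17)
    # short sequence with a planted repeat so both strands matter
    seg = random_seq(local, 40)
    text = random_seq(local, 150) + seg + random_seq(local, 60) + revcomp(seg)
    ref = toy_genome("r", text)
    k = 11
    mask = repetitive_mask(ref, k)
    oracle = np.zeros(len(text), dtype=bool)
    for i in range(len(text) - k + 1):
        km = text[i:i + k]
        hits = len(re.findall(f"(?={re.escape(km)})", text))
        hits += len(re.findall(f"(?={re.escape(revcomp(km))})", text))
        if km == revcomp(km):
            hits -= 1
        if hits > 1:
            oracle[i:i + k] = True
    assert (mask == oracle).all()


def test_aln_flag_threshold_and_isolated_snp():
    dense = [_col(c, "AC") for c in range(11)]  # 11 variants in 11 columns
    flag_alignment_quality(dense, window_size=100, max_window_variants=10)
    assert all(FLAG_ALN in v.flags for v in dense)
    sparse = [_col(c * 50, "AC") for c in range(5)]
    flag_alignment_quality(sparse, window_size=100, max_window_variants=10)
    assert all(FLAG_ALN not in v.flags for v in sparse)


@pytest.mark.parametrize("trial", range(10))
def test_aln_flags_match_quadratic_recount(trial):
    local = random.Random(600 + trial)
    cols = sorted(local.sample(range(2000), 120))
    variants = [_col(c, "AC") for c in cols]
    ws, mx = 100, 10
    flag_alignment_quality(variants, window_size=ws, max_window_variants=mx)
    lo_half = ws // 2
    hi_half = ws - lo_half - 1
    for v in variants:
        n = sum(1 for c in cols if v.col - lo_half <= c <= v.col + hi_half)
        assert (FLAG_ALN in v.flags) == (n > mx), v.col


def test_lcb_flag_conservation():
    cols = [_col(0, "AC", lcb_id=1), _col(1, "AG", lcb_id=2)]
    flag_lcb_size(cols, dropped_lcb_ids={2})
    assert FLAG_LCB not in cols[0].flags
    assert FLAG_LCB in cols[1].flags


def _pattern_col(col, carriers, n=8):
    alleles = "".join("T" if i in carriers else "A" for i in range(n))
    return _col(col, alleles)


def test_phi_clonal_no_flags():
    # nested clade patterns from a clonal tree: never four-gamete violating
    cols = []
    for k in range(30):
        carriers = {0, 1, 2, 3} if k % 3 == 0 else ({0, 1} if k % 3 == 1 else {6, 7})
        cols.append(_pattern_col(k * 40, carriers))
    p = phi_recombination(cols, 8, phi_window=1000, phi_permutations=200,
                          phi_alpha=0.05, seed=3)
    assert p == 1.0
    assert all(FLAG_REC not in v.flags for v in cols)


def test_phi_mosaic_flagged():
    # two incompatible splits segregated in space: nearby pairs are
    # compatible, permutation mixes them -> significant, REC flags near
    # the mosaic junction
    cols = []
    for k in range(25):
        cols.append(_pattern_col(k * 200, {0, 1, 2, 3}))
    for k in range(25):
        cols.append(_pattern_col(5000 + k * 200, {2, 3, 4, 5}))
    p = phi_recombination(cols, 8, phi_window=1000, phi_permutations=1000,
                          phi_alpha=0.05, seed=3)
    assert p is not None and p <= 0.05
    flagged = [v for v in cols if FLAG_REC in v.flags]
    assert flagged
    # flags concentrate around the junction at column 5000
    assert all(4000 <= v.col <= 6000 for v in flagged)


def test_phi_pvalues_roughly_uniform_under_null():
    pvals = []
    for rep in range(15):
        local = random.Random(rep)
        cols = []
        for k in range(30):
            carriers = frozenset(local.sample(range(8), 4))
            cols.append(_pattern_col(k * 100, carriers))
        p = phi_recombination(cols, 8, phi_window=500, phi_permutations=200,
                              phi_alpha=1e-9, seed=rep)
        if p is not None:
            pvals.append(p)
    assert len(pvals) >= 10
    # no systematic inflation toward significance
    assert np.mean(pvals) > 0.2


def test_phi_skipped_below_four_genomes():
    cols = [_col(0, "ACT"), _col(10, "TGA")]
    assert phi_recombination(cols, 3, 1000, 100, 0.05, seed=1) is None
    assert all(not v.flags for v in cols)


def test_phi_deterministic_given_seed():
    local = random.Random(5)
    cols1 = []
    cols2 = []
    for k in range(40):
        carriers = frozenset(local.sample(range(8), local.choice([2, 3, 4])))
        cols1.append(_pattern_col(k * 120, carriers))
        cols2.append(_pattern_col(k * 120, carriers))
    p1 = phi_recombination(cols1, 8, 800, 300, 0.5, seed=9)
    p2 = phi_recombination(cols2, 8, 800, 300, 0.5, seed=9)
    assert p1 == p2
    assert [sorted(v.flags) for v in cols1] == [sorted(v.flags) for v in cols2]


def test_core_snps_filtering_rules():
    clean = _col(0, "ACAA")
    flagged = _col(1, "AGAA")
    flagged.flags.add(FLAG_REP)
    indel = _col(2, "A-AA")
    ambiguous = _col(3, "ANCA")
    snps = core_snps([clean, flagged, indel, ambiguous], ["a", "b", "c", "d"])
    assert snps.columns == [clean]
    assert snps.row("a") == "A"
    # filters only ever remove columns relative to no-filter mode
    unfiltered = core_snps([clean, _col(1, "AGAA")], ["a", "b", "c", "d"])
    assert len(snps) <= len(unfiltered)


def test_qual_flag_never_set(run8):
    _, _, result = run8
    assert all(FLAG_QUAL not in v.flags for v in result.columns)


def test_filter_idempotence(run8):
    from coremum.variants import FilterConfig, apply_filters

    _, _, result = run8
    before = [frozenset(v.flags) for v in result.columns]
    dropped = {b.lcb.id for b in result.core.lcbs if not b.lcb.kept}
    apply_filters(
        result.columns, result.reference, dropped, len(result.genomes),
        FilterConfig(seed=result.config.seed),
    )
    assert [frozenset(v.flags) for v in result.columns] == before
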