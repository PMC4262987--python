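"""Distances, neighbor joining and Newick round-trips."""

import math
import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from coremum.errors import NewickParseError, SaturationError
from coremum.phylogeny import (
    DistanceMatrix,
    canonicalize,
    jukes_cantor,
    nj_tree,
    read_newick,
    snp_distances,
    tree_to_newick,
    write_newick,
)
from coremum.variants import SnpMatrix, VariantColumn


def _matrix(rows: dict[str, str]) -> SnpMatrix:
    ids = list(rows)
    ncol = len(next(iter(rows.values())))
    cols = [
        VariantColumn(
            lcb_id=0, col=i, ref_pos=i,
            alleles="".join(rows[g][i] for g in ids),
            positions=tuple([i] * len(ids)),
        )
        for i in range(ncol)
    ]
    return SnpMatrix(genome_ids=ids, columns=cols)


def test_jc_formula_and_saturation():
    assert jukes_cantor(0.0) == 0.0
    p = 0.02
    assert jukes_cantor(p) == pytest.approx(-0.75 * math.log(1 - 0.08 / 3))
    with pytest.raises(SaturationError):
        jukes_cantor(0.75)


def test_snp_distances_counts_non_n_columns():
    m = _matrix({"a": "ACGTACGTAC" * 10, "b": "ACGTACGTAC" * 10})
    dm = snp_distances(m)
    assert dm.d[0, 1] == 0.0
    rows = {"a": "A" * 100, "b": "A" * 98 + "CC"}
    dm = snp_distances(_matrix(rows))
    assert dm.d[0, 1] == pytest.approx(jukes_cantor(0.02))
    # N columns are excluded pairwise
    rows = {"a": "AAAN", "b": "AAAC"}
    assert snp_distances(_matrix(rows)).d[0, 1] == 0.0


def test_nj_exact_recovery_on_additive_matrix():
    # tree: ((a:1,b:2):3,(c:4,d:5)) -> unique additive distances
    ids = ["a", "b", "c", "d"]
    d = np.array([
        [0, 3, 8, 9],
        [3, 0, 9, 10],
        [8, 9, 0, 9],
        [9, 10, 9, 0],
    ], dtype=float)
    tree = nj_tree(DistanceMatrix(ids, d))
    assert tree_to_newick(tree).strip() == "((a:1,b:2):3,c:4,d:5);"


def test_nj_three_taxa_closed_form():
    ids = ["a", "b", "c"]
    d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(ids, d))
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    assert lengths == {"a": 1.0, "b": 3.0, "c": 5.0}


def test_nj_leaf_conservation_and_nonnegative_branches():
    rng = random.Random(11)
    ids = [f"t{i}" for i in range(9)]
    d = np.zeros((9, 9))
    for i in range(9):
        for j in range(i + 1, 9):
            d[i, j] = d[j, i] = rng.uniform(0.01, 0.3)
    tree = nj_tree(DistanceMatrix(ids, d))
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    assert labels == sorted(ids)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0


@pytest.mark.parametrize("trial", range(5))
def test_nj_topology_agrees_with_skbio(trial):
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = random.Random(40 + trial)
    # additive matrix from a random binary tree with positive branches
    n = 7
    ids = [f"t{i}" for i in range(n)]
    sim = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=random.Random(trial),
    )
    for i, leaf in enumerate(sim.leaf_node_iter()):
        leaf.taxon.label = ids[i]
    pdm = sim.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    taxa = {t.label: t for t in sim.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    mine = nj_tree(DistanceMatrix(ids, d))
    other = skbio_nj(SkbioDM(d, ids))
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=tree_to_newick(mine), schema="newick",
                           taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=str(other).strip(), schema="newick",
                           taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert treecompare.symmetric_difference(t1, t2) == 0


def test_newick_round_trip(tmp_path):
    path = tmp_path / "t.nwk"
    tree = nj_tree(DistanceMatrix(
        ["a", "b", "c", "d"],
        np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
                 dtype=float),
    ))
    write_newick(tree, path)
    back = read_newick(path)
    assert tree_to_newick(back) == tree_to_newick(tree)


def test_newick_parse_basics_and_errors():
    t = read_newick("(a:1,b:2);")
    assert len(t.leaf_nodes()) == 2
    with pytest.raises(NewickParseError):
        read_newick("((a:1,b:2;")


def test_canonicalize_orders_children():
    t1 = read_newick("((b:1,a:1):1,c:1);")
    t2 = read_newick("((a:1,b:1):1,c:1);")
    assert tree_to_newick(canonicalize(t1)) == tree_to_newick(canonicalize(t2))
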