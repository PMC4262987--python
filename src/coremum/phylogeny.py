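"""SNP phylogeny: Jukes-Cantor distances, neighbor joining, Newick IO.

Distances are p-distances over SNP columns (positions where both alleles
are non-N), Jukes-Cantor corrected: d = -(3/4) ln(1 - 4p/3).  Trees are
built by neighbor joining with deterministic tie-breaking and reported
unrooted; branch lengths are in substitutions per SNP site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import dendropy
import numpy as np

from .errors import NewickParseError, SaturationError
from .variants import SnpMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal


def jukes_cantor(p: float) -> float:
    """JC69 distance for a p-distance; saturates at p >= 0.75."""
    if p >= 0.75:
        raise SaturationError(
            f"pairwise SNP p-distance {p:.3f} >= 0.75 is saturated; "
            "input genomes are not intraspecific"
        )
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def snp_distances(matrix: SnpMatrix) -> DistanceMatrix:
    """Pairwise JC-corrected distances from the core SNP allele matrix."""
    ids = matrix.genome_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 genomes")
    if len(matrix) < 1:
        raise ValueError("need at least 1 SNP column")
    rows = np.array(
        [np.frombuffer(matrix.row(g).encode(), dtype=np.uint8) for g in ids]
    )
    n = len(ids)
    d = np.zeros((n, n))
    valid_base = rows != ord("N")
    for i in range(n):
        for j in range(i + 1, n):
            both = valid_base[i] & valid_base[j]
            total = int(both.sum())
            if total == 0:
                raise SaturationError(
                    f"no comparable SNP columns between {ids[i]} and {ids[j]}"
                )
            mism = int((rows[i][both] != rows[j][both]).sum())
            d[i, j] = d[j, i] = jukes_cantor(mism / total)
    return DistanceMatrix(ids=list(ids), d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[tuple["_Node", float]] = []

    def min_leaf(self) -> str:
        if not self.children:
            return self.label
        return min(c.min_leaf() for c, _ in self.children)

    def newick(self, fmt: str = ".6g") -> str:
        if not self.children:
            return self.label
        kids = sorted(self.children, key=lambda cb: cb[0].min_leaf())
        inner = ",".join(
            f"{c.newick(fmt)}:{bl:{fmt}}" for c, bl in kids
        )
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of subtree labels; negative branch lengths are clamped to zero
    with the deficit transferred to the sibling branch.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[_Node] = [_Node(label=g) for g in dm.ids]
    labels = [g for g in dm.ids]  # canonical label = min leaf under node
    D = dm.d.astype(float).copy()
    active = list(range(n))

    if n == 2:
        root = _Node()
        root.children = [(nodes[0], D[0, 1] / 2), (nodes[1], D[0, 1] / 2)]
        return _to_dendropy(root)

    while len(active) > 3:
        k = len(active)
        # Q matrix over active nodes
        best = None
        totals = {i: sum(D[i, j] for j in active if j != i) for i in active}
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                q = (k - 2) * D[i, j] - totals[i] - totals[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        di = (D[i, j] + (totals[i] - totals[j]) / (k - 2)) / 2
        dj = D[i, j] - di
        di, dj = _clamp_pair(di, dj)
        parent = _Node()
        parent.children = [(nodes[i], di), (nodes[j], dj)]
        # distances to the new node
        new_row = {}
        for x in active:
            if x in (i, j):
                continue
            new_row[x] = (D[i, x] + D[j, x] - D[i, j]) / 2
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        idx = len(nodes) - 1
        for x, val in new_row.items():
            D[idx, x] = D[x, idx] = val
        active = [x for x in active if x not in (i, j)] + [idx]

    i, j, l = active
    # three-point formulas for the final star
    bi = (D[i, j] + D[i, l] - D[j, l]) / 2
    bj = (D[i, j] + D[j, l] - D[i, l]) / 2
    bl = (D[i, l] + D[j, l] - D[i, j]) / 2
    root = _Node()
    branches = [(nodes[i], bi), (nodes[j], bj), (nodes[l], bl)]
    branches = [(c, max(0.0, b)) for c, b in branches]
    root.children = branches
    return _to_dendropy(root)


def _clamp_pair(di: float, dj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling."""
    if di < 0:
        dj = max(0.0, dj + di)
        di = 0.0
    if dj < 0:
        di = max(0.0, di + dj)
        dj = 0.0
    return di, dj


def _to_dendropy(root: _Node) -> dendropy.Tree:
    newick = root.newick() + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def canonicalize(tree: dendropy.Tree) -> dendropy.Tree:
    """Sort children by their lexicographically smallest descendant leaf."""

    def key(node):
        return min(leaf.taxon.label for leaf in node.leaf_iter())

    for node in tree.preorder_node_iter():
        if node.child_nodes():
            node.set_child_nodes(sorted(node.child_nodes(), key=key))
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    canonicalize(tree)
    out = StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )
    return out.getvalue().strip() + "\n"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize canonicalized, branch lengths at 6 significant digits."""
    Path(path).write_text(tree_to_newick(tree))


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree; malformed input raises NewickParseError."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        data = Path(source).read_text()
    else:
        data = str(source)
    try:
        tree = dendropy.Tree.get(data=data, schema="newick")
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree
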