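"""Simulation of intraspecific genome evolution with known truth.

A random ancestor (optionally with planted repeats) is evolved along a
balanced binary tree (or star / user-supplied topology): per branch,
substitutions are drawn as a binomial over sites with an HKY-style
transition bias (transition : each transversion = tstv : 1), no indels.
Each leaf genome then receives a Poisson number of non-overlapping
rearrangements -- inversions and translocations in equal proportion,
sizes geometric around the configured mean.  The simulator records the
complete truth: the tree, per-branch substitution events, each leaf's
SNPs against the ancestor, every rearrangement breakpoint, and the
leaf-to-ancestor coordinate map.

All randomness is driven by the config seed; identical configs produce
byte-identical genomes and truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import Genome, revcomp, write_fasta

_BASES = "ACGT"
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
_TRANSVERSIONS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    length: int = 100_000
    gc: float = 0.5
    leaves: int = 32
    topology: str = "balanced"          # balanced | star
    user_newick: str | None = None      # overrides topology when given
    rate: float = 1e-4                  # substitutions / site / branch
    tstv: float = 4.0
    n_rearrangements: float = 10.0      # mean count per leaf genome
    rearrangement_size: float = 1000.0  # mean bases
    planted_repeats: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 0.75:
            raise ValueError("rate must be in [0, 0.75)")
        if self.tstv <= 0:
            raise ValueError("tstv must be positive")
        if self.leaves < 2:
            raise ValueError("need at least 2 leaves")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated genomes."""

    ancestor: str
    tree_newick: str
    branch_events: dict[str, list[tuple[int, str, str]]]
    snps: dict[str, dict[int, str]]            # gid -> anc pos -> allele
    breakpoints: dict[str, list[int]]          # gid -> anc positions
    rearrangements: dict[str, list[tuple[str, int, int, int | None]]]
    segmap: dict[str, list[tuple[int, int, int, str]]]
    # gid -> ordered (leaf_start, anc_start, anc_end, strand)

    def leaf_to_anc(self, gid: str, pos: int) -> tuple[int, str]:
        """Map a leaf-genome position to (ancestor position, strand)."""
        pieces = self.segmap[gid]
        lo, hi = 0, len(pieces) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if pieces[mid][0] <= pos:
                lo = mid
            else:
                hi = mid - 1
        leaf_start, anc_start, anc_end, strand = pieces[lo]
        off = pos - leaf_start
        if off >= anc_end - anc_start:
            raise ValueError(f"position {pos} unmappable in {gid}")
        if strand == "+":
            return anc_start + off, "+"
        return anc_end - 1 - off, "-"

    def all_breakpoints(self) -> list[tuple[str, int]]:
        return [(gid, p) for gid, bps in self.breakpoints.items() for p in bps]


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("name", "length", "children")

    def __init__(self, name: str, length: float):
        self.name = name
        self.length = length
        self.children: list["_SimNode"] = []

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.8g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}){self.name}:{self.length:.8g}"


def _balanced_tree(leaf_names: list[str], rate: float) -> _SimNode:
    counter = [0]

    def build(names: list[str]) -> _SimNode:
        if len(names) == 1:
            return _SimNode(names[0], rate)
        counter[0] += 1
        node = _SimNode(f"n{counter[0]}", rate)
        half = (len(names) + 1) // 2
        node.children = [build(names[:half]), build(names[half:])]
        return node

    root = build(leaf_names)
    root.length = 0.0  # no branch above the root
    return root


def _star_tree(leaf_names: list[str], rate: float) -> _SimNode:
    root = _SimNode("n1", 0.0)
    root.children = [_SimNode(n, rate) for n in leaf_names]
    return root


def _tree_from_newick(text: str) -> _SimNode:
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")
    counter = [0]

    def convert(node) -> _SimNode:
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_")
        else:
            counter[0] += 1
            name = f"n{counter[0]}"
        out = _SimNode(name, node.edge.length or 0.0)
        out.children = [convert(c) for c in node.child_nodes()]
        return out

    return convert(tree.seed_node)


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, p: float, tstv: float, rng: np.random.Generator):
    """One branch of evolution; returns (child seq, event list)."""
    child = seq.copy()
    if p <= 0:
        return child, []
    n = rng.binomial(seq.size, p)
    if n == 0:
        return child, []
    pos = np.sort(rng.choice(seq.size, size=n, replace=False))
    # tstv is the expected transition:transversion COUNT ratio
    p_ts = tstv / (tstv + 1.0)
    events = []
    for x in pos:
        old = int(child[x])
        if rng.random() < p_ts:
            new = _TRANSITION[old]
        else:
            new = _TRANSVERSIONS[old][rng.integers(0, 2)]
        child[x] = new
        events.append((int(x), _BASES[old], _BASES[new]))
    return child, events


def _sample_rearrangements(L, n_mean, size_mean, rng):
    """Non-overlapping rearrangement operations in ancestor coordinates."""
    k = int(rng.poisson(n_mean))
    segments: list[tuple[int, int]] = []
    tries = 0
    while len(segments) < k and tries < 200 * max(k, 1):
        tries += 1
        # sizes narrowly around the configured mean ("~1 kb segments");
        # the Poisson count is what carries the "average of 10"
        size = int(round(rng.normal(size_mean, 0.1 * size_mean)))
        if size < 10 or size >= L:
            continue
        s = int(rng.integers(0, L - size))
        e = s + size
        if any(not (e <= a or s >= b) for a, b in segments):
            continue
        segments.append((s, e))
    ops = []
    for s, e in sorted(segments):
        if rng.random() < 0.5:
            ops.append(("inversion", s, e, None))
        else:
            while True:
                x = int(rng.integers(0, L + 1))
                if all(not (a < x < b) for a, b in segments):
                    break
            ops.append(("translocation", s, e, x))
    return ops


def _split_pieces(pieces, coord):
    """Split the '+' piece containing an ancestor coordinate."""
    for i, (a, b, strand) in enumerate(pieces):
        if strand == "+" and a < coord < b:
            pieces[i:i + 1] = [(a, coord, "+"), (coord, b, "+")]
            return


def _apply_rearrangements(L, ops):
    """Apply operations to the identity piece list [(0, L, '+')]."""
    pieces: list[tuple[int, int, str]] = [(0, L, "+")]
    breakpoints: set[int] = set()
    # inversions first: in-place, do not move coordinates
    for kind, s, e, _ in ops:
        if kind != "inversion":
            continue
        _split_pieces(pieces, s)
        _split_pieces(pieces, e)
        idx = [i for i, (a, b, _st) in enumerate(pieces) if a >= s and b <= e]
        inv = [(a, b, "-") for a, b, _st in reversed([pieces[i] for i in idx])]
        pieces[idx[0]:idx[-1] + 1] = inv
        breakpoints.update((s, e))
    for kind, s, e, x in ops:
        if kind != "translocation":
            continue
        _split_pieces(pieces, s)
        _split_pieces(pieces, e)
        idx = [i for i, (a, b, st) in enumerate(pieces)
               if st == "+" and a >= s and b <= e]
        moved = [pieces[i] for i in idx]
        for i in reversed(idx):
            del pieces[i]
        _split_pieces(pieces, x)
        # insert in leaf order right after the piece ending at ancestor
        # coordinate x (or before the piece starting at x)
        at = len(pieces)
        for i, (a, b, _st) in enumerate(pieces):
            if b == x:
                at = i + 1
                break
            if a == x:
                at = i
                break
        pieces[at:at] = moved
        breakpoints.update((s, e, x))
    return pieces, sorted(breakpoints)


def _leaf_sequence(evolved: str, pieces) -> tuple[str, list]:
    parts = []
    segmap = []
    off = 0
    for a, b, strand in pieces:
        seg = evolved[a:b]
        if strand == "-":
            seg = revcomp(seg)
        parts.append(seg)
        segmap.append((off, a, b, strand))
        off += b - a
    return "".join(parts), segmap


def simulate_evolution(config: SimConfig) -> tuple[list[Genome], SimTruth]:
    """Simulate genomes and the full evaluation truth."""
    rng = np.random.default_rng(config.seed)
    L = config.length
    p = np.array([(1 - config.gc) / 2, config.gc / 2,
                  config.gc / 2, (1 - config.gc) / 2])
    anc = rng.choice(4, size=L, p=p).astype(np.uint8)

    for seg_len, copies in config.planted_repeats:
        src = int(rng.integers(0, L - seg_len))
        for _ in range(max(0, copies - 1)):
            dst = int(rng.integers(0, L - seg_len))
            anc[dst:dst + seg_len] = anc[src:src + seg_len]

    leaf_names = [f"g{i:02d}" for i in range(config.leaves)]
    if config.user_newick:
        root = _tree_from_newick(config.user_newick)
    elif config.topology == "star":
        root = _star_tree(leaf_names, config.rate)
    elif config.topology == "balanced":
        root = _balanced_tree(leaf_names, config.rate)
    else:
        raise ValueError(f"unknown topology {config.topology!r}")

    branch_events: dict[str, list] = {}
    leaf_arrays: dict[str, np.ndarray] = {}

    def walk(node: _SimNode, seq: np.ndarray) -> None:
        for child in node.children:
            cseq, events = _mutate(seq, child.length, config.tstv, rng)
            branch_events[child.name] = events
            if child.children:
                walk(child, cseq)
            else:
                leaf_arrays[child.name] = cseq

    if root.children:
        walk(root, anc)
    else:  # degenerate single-node tree
        leaf_arrays[root.name] = anc.copy()

    anc_str = "".join(_BASES[b] for b in anc)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)

    genomes: list[Genome] = []
    snps: dict[str, dict[int, str]] = {}
    breakpoints: dict[str, list[int]] = {}
    rearrangements: dict[str, list] = {}
    segmap: dict[str, list] = {}
    for name in leaf_names:
        arr = leaf_arrays[name]
        diff = np.nonzero(arr != anc)[0]
        snps[name] = {int(i): _BASES[arr[i]] for i in diff}
        evolved = lut[arr].tobytes().decode()
        ops = _sample_rearrangements(
            L, config.n_rearrangements, config.rearrangement_size, rng
        )
        pieces, bps = _apply_rearrangements(L, ops)
        seq, smap = _leaf_sequence(evolved, pieces)
        genomes.append(Genome(id=name, contigs=[("chr", seq)]))
        breakpoints[name] = bps
        rearrangements[name] = ops
        segmap[name] = smap

    truth = SimTruth(
        ancestor=anc_str,
        tree_newick=root.newick() + ";",
        branch_events=branch_events,
        snps=snps,
        breakpoints=breakpoints,
        rearrangements=rearrangements,
        segmap=segmap,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# on-disk truth
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir: str | Path, genomes: list[Genome], truth: SimTruth
) -> None:
    """Write genome FASTAs plus tab-separated truth tables."""
    out = Path(out_dir)
    gdir = out / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_fasta(gdir / f"{g.id}.fa", [(n, s) for n, s in g.contigs])
    write_fasta(out / "ancestor.fa", [("ancestor", truth.ancestor)])
    (out / "truth_tree.nwk").write_text(truth.tree_newick + "\n")
    with open(out / "truth_snps.tsv", "w") as fh:
        fh.write("genome\tanc_pos\tanc_base\tallele\n")
        for gid in sorted(truth.snps):
            for pos in sorted(truth.snps[gid]):
                fh.write(
                    f"{gid}\t{pos}\t{truth.ancestor[pos]}\t{truth.snps[gid][pos]}\n"
                )
    with open(out / "truth_breakpoints.tsv", "w") as fh:
        fh.write("genome\tanc_pos\n")
        for gid in sorted(truth.breakpoints):
            for pos in truth.breakpoints[gid]:
                fh.write(f"{gid}\t{pos}\n")
    with open(out / "truth_segments.tsv", "w") as fh:
        fh.write("genome\tleaf_start\tanc_start\tanc_end\tstrand\n")
        for gid in sorted(truth.segmap):
            for leaf_start, a, b, strand in truth.segmap[gid]:
                fh.write(f"{gid}\t{leaf_start}\t{a}\t{b}\t{strand}\n")
    with open(out / "truth_branch_events.json", "w") as fh:
        json.dump(truth.branch_events, fh)


def load_truth(out_dir: str | Path) -> SimTruth:
    """Reload a truth set written by :func:`write_dataset`."""
    out = Path(out_dir)
    ancestor = "".join(
        line.strip() for line in
        (out / "ancestor.fa").read_text().splitlines()[1:]
    )
    tree = (out / "truth_tree.nwk").read_text().strip()
    snps: dict[str, dict[int, str]] = {}
    for line in (out / "truth_snps.tsv").read_text().splitlines()[1:]:
        gid, pos, _, allele = line.split("\t")
        snps.setdefault(gid, {})[int(pos)] = allele
    breakpoints: dict[str, list[int]] = {}
    for line in (out / "truth_breakpoints.tsv").read_text().splitlines()[1:]:
        gid, pos = line.split("\t")
        breakpoints.setdefault(gid, []).append(int(pos))
    segmap: dict[str, list] = {}
    for line in (out / "truth_segments.tsv").read_text().splitlines()[1:]:
        gid, ls, a, b, strand = line.split("\t")
        segmap.setdefault(gid, []).append((int(ls), int(a), int(b), strand))
    with open(out / "truth_branch_events.json") as fh:
        branch_events = {
            k: [(int(p), f, t) for p, f, t in v]
            for k, v in json.load(fh).items()
        }
    for gid in snps:
        breakpoints.setdefault(gid, [])
    return SimTruth(
        ancestor=ancestor,
        tree_newick=tree,
        branch_events=branch_events,
        snps=snps,
        breakpoints=breakpoints,
        rearrangements={},
        segmap=segmap,
    )
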