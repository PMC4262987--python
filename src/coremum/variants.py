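"""Variant-column extraction and the five-criterion SNP filter.

Every polymorphic column of the core alignment becomes a
:class:`VariantColumn`.  Columns are then flagged by up to five criteria:

* ``REP`` -- the reference position lies in repetitive sequence (a
  reference k-mer covering it occurs more than once on either strand);
* ``LCB`` -- the column originates from a block below the LCB weight
  threshold (kept in the archive, excluded from core SNPs);
* ``ALN`` -- too many variant columns (SNPs and indel columns together)
  inside the alignment window centred on the column;
* ``QUAL`` -- reserved for read-based base-quality evidence; never set
  by this package;
* ``REC`` -- the column lies in a region with a significant pairwise
  homoplasy (PHI) signal of recombination.

Only unflagged, indel-free, N-free columns are reliable core-genome SNPs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .gapalign import CoreAlignment
from .sequence_io import Genome, revcomp

log = logging.getLogger(__name__)

FLAG_REP = "REP"
FLAG_LCB = "LCB"
FLAG_ALN = "ALN"
FLAG_QUAL = "QUAL"
FLAG_REC = "REC"


@dataclass
class FilterConfig:
    """Thresholds for the column filters (defaults recorded in run
    metadata; the flag vocabulary is fixed)."""

    repeat_kmer: int = 21
    window_size: int = 100
    max_window_variants: int = 10
    min_lcb_weight: int = 63
    phi_window: int = 1000
    phi_permutations: int = 1000
    phi_alpha: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("repeat_kmer", "window_size", "max_window_variants",
                     "min_lcb_weight", "phi_window", "phi_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.phi_alpha < 1:
            raise ValueError("phi_alpha must be in (0, 1)")


@dataclass
class VariantColumn:
    """One polymorphic core-alignment column."""

    lcb_id: int
    col: int                       # column index within the LCB
    ref_pos: int | None            # None when the reference allele is a gap
    alleles: str                   # one character per genome, genome order
    positions: tuple[int | None, ...]  # forward-strand position per genome
    flags: set[str] = field(default_factory=set)

    @property
    def is_indel(self) -> bool:
        return "-" in self.alleles


def extract_columns(core: CoreAlignment) -> list[VariantColumn]:
    """All polymorphic columns (>= 2 distinct non-N alleles), ordered by
    LCB then column; monomorphic columns are omitted."""
    gids = core.genome_ids
    ref_id = gids[0]
    out: list[VariantColumn] = []
    for block in core.lcbs:
        lcb = block.lcb
        # per-genome walk state: current forward-strand position and step
        pos: dict[str, int] = {}
        step: dict[str, int] = {}
        for gid in gids:
            lo, hi = lcb.extent(gid)
            if lcb.orientation(gid):
                pos[gid] = hi - 1
                step[gid] = -1
            else:
                pos[gid] = lo
                step[gid] = 1
        col = 0
        for kind, payload in block.segments:
            if kind == "anchor":
                n = len(payload)
                for gid in gids:
                    pos[gid] += step[gid] * n
                col += n
                continue
            rows = {gid: payload.rows[gid] for gid in gids}
            for k in range(payload.width):
                alleles = []
                col_positions = []
                for gid in gids:
                    c = rows[gid][k]
                    alleles.append(c)
                    if c == "-":
                        col_positions.append(None)
                    else:
                        col_positions.append(pos[gid])
                        pos[gid] += step[gid]
                distinct = set(alleles) - {"N"}
                if len(distinct) >= 2:
                    ref_allele = alleles[0]
                    ref_pos = col_positions[0] if ref_allele != "-" else None
                    out.append(
                        VariantColumn(
                            lcb_id=lcb.id,
                            col=col,
                            ref_pos=ref_pos,
                            alleles="".join(alleles),
                            positions=tuple(col_positions),
                        )
                    )
                col += 1
    order = {b.lcb.id: i for i, b in enumerate(core.lcbs)}
    out.sort(key=lambda v: (order[v.lcb_id], v.col))
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def repetitive_mask(reference: Genome, k: int) -> np.ndarray:
    """Boolean mask over the reference concatenation: True where some
    covering k-mer occurs more than once (counting both strands).
    K-mers containing N or a contig separator never match and are
    ignored."""
    text = reference.concat
    n = len(text)
    mask = np.zeros(n, dtype=bool)
    if n < k:
        return mask
    counts: Counter[str] = Counter()
    valid = set("ACGT")
    kmers: list[tuple[int, str]] = []
    run_ok = 0
    for i, c in enumerate(text):
        run_ok = run_ok + 1 if c in valid else 0
        if run_ok >= k:
            start = i - k + 1
            km = text[start:i + 1]
            kmers.append((start, km))
            counts[km] += 1
    diff = np.zeros(n + 1, dtype=np.int64)
    for start, km in kmers:
        if counts[km] + counts[revcomp(km)] - (km == revcomp(km)) > 1:
            diff[start] += 1
            diff[start + k] -= 1
    return np.cumsum(diff[:-1]) > 0


def flag_repetitive(
    columns: list[VariantColumn], reference: Genome, repeat_kmer: int
) -> None:
    """Set REP on columns whose reference position is repetitive."""
    mask = repetitive_mask(reference, repeat_kmer)
    for v in columns:
        if v.ref_pos is not None and mask[v.ref_pos]:
            v.flags.add(FLAG_REP)


def flag_alignment_quality(
    columns: list[VariantColumn], window_size: int, max_window_variants: int
) -> None:
    """Set ALN on every variant column whose centred window of
    ``window_size`` alignment columns contains more than
    ``max_window_variants`` variant columns (SNPs and indels together)."""
    half_lo = window_size // 2
    half_hi = window_size - half_lo - 1
    by_lcb: dict[int, list[VariantColumn]] = {}
    for v in columns:
        by_lcb.setdefault(v.lcb_id, []).append(v)
    for group in by_lcb.values():
        cols = [v.col for v in group]  # sorted within an LCB
        lo = 0
        hi = 0
        for idx, v in enumerate(group):
            while cols[lo] < v.col - half_lo:
                lo += 1
            if hi <= idx:
                hi = idx
            while hi < len(cols) and cols[hi] <= v.col + half_hi:
                hi += 1
            if hi - lo > max_window_variants:
                v.flags.add(FLAG_ALN)


def flag_lcb_size(columns: list[VariantColumn], dropped_lcb_ids: set[int]) -> None:
    """Set LCB on columns originating from weight-filtered blocks."""
    for v in columns:
        if v.lcb_id in dropped_lcb_ids:
            v.flags.add(FLAG_LCB)


# ---------------------------------------------------------------------------
# PHI recombination filter
# ---------------------------------------------------------------------------

def _binarize(alleles: str) -> np.ndarray | None:
    """Major/minor binarization of one column; None when the site has
    missing data (N or gap) or is not polymorphic after binarization."""
    if "N" in alleles or "-" in alleles:
        return None
    counts = Counter(alleles)
    major = max(sorted(counts), key=lambda a: counts[a])
    x = np.frombuffer(alleles.encode(), dtype=np.uint8) != ord(major)
    if not x.any():
        return None
    return x


def phi_recombination(
    columns: list[VariantColumn],
    n_genomes: int,
    phi_window: int,
    phi_permutations: int,
    phi_alpha: float,
    seed: int,
    lcb_offsets: dict[int, int] | None = None,
) -> float | None:
    """Pairwise homoplasy test; sets REC flags, returns the p-value.

    Sites are binarized to major/minor allele; a site pair is
    incompatible when all four gamete combinations occur.  The statistic
    is the mean incompatibility over site pairs within ``phi_window``
    alignment columns of each other; significance comes from permuting
    the assignment of allele patterns to site positions.  Under clonal
    evolution without recurrent mutation no pair is incompatible and the
    test is a guaranteed no-op.  With fewer than 4 genomes the test has
    no power and is skipped (logged).
    """
    if n_genomes < 4:
        log.warning("PHI recombination test skipped: fewer than 4 genomes")
        return None
    # global column coordinate: LCB offset + column
    if lcb_offsets is None:
        lcb_offsets = {}
        off = 0
        seen: dict[int, int] = {}
        for v in columns:
            if v.lcb_id not in seen:
                seen[v.lcb_id] = off
                off += 10 ** 9  # separate LCBs by more than any window
        lcb_offsets = seen

    sites: list[tuple[int, np.ndarray, VariantColumn]] = []
    for v in columns:
        x = _binarize(v.alleles)
        if x is None:
            continue
        if int(x.sum()) < 2 or int((~x).sum()) < 2:
            continue  # uninformative for the four-gamete condition
        sites.append((lcb_offsets[v.lcb_id] + v.col, x, v))
    m = len(sites)
    if m < 2:
        return None
    sites.sort(key=lambda t: t[0])
    coords = np.array([t[0] for t in sites], dtype=np.int64)
    X = np.stack([t[1] for t in sites]).astype(np.int8)

    # deduplicate allele patterns; incompatibility depends only on the pair
    uniq, pid = np.unique(X, axis=0, return_inverse=True)
    U = uniq.astype(np.int64)
    n11 = (U @ U.T) > 0
    n10 = (U @ (1 - U).T) > 0
    n01 = ((1 - U) @ U.T) > 0
    n00 = ((1 - U) @ (1 - U).T) > 0
    incompat = n11 & n10 & n01 & n00

    I_list: list[int] = []
    J_list: list[int] = []
    hi = 0
    for i in range(m):
        if hi <= i:
            hi = i + 1
        while hi < m and coords[hi] - coords[i] <= phi_window:
            hi += 1
        I_list.extend([i] * (hi - i - 1))
        J_list.extend(range(i + 1, hi))
    if not I_list:
        return None
    I = np.array(I_list)
    J = np.array(J_list)

    obs_pair_incompat = incompat[pid[I], pid[J]]
    phi_obs = float(obs_pair_incompat.mean())

    # if no pattern pair at all is incompatible, permutation cannot lower
    # the statistic below the observed 0: clonal shortcut
    if not incompat[np.ix_(np.unique(pid), np.unique(pid))].any():
        return 1.0

    rng = np.random.default_rng(seed)
    leq = 0
    for _ in range(phi_permutations):
        perm = rng.permutation(m)
        phi_p = float(incompat[pid[perm[I]], pid[perm[J]]].mean())
        if phi_p <= phi_obs + 1e-12:
            leq += 1
    p_value = (1 + leq) / (phi_permutations + 1)

    if p_value <= phi_alpha:
        spans = [
            (coords[i], coords[j])
            for i, j in zip(I[obs_pair_incompat], J[obs_pair_incompat])
        ]
        for coord, _, v in sites:
            if any(lo <= coord <= hi for lo, hi in spans):
                v.flags.add(FLAG_REC)
        log.info(
            "PHI test significant (p=%.4g): flagged recombinant region(s)",
            p_value,
        )
    return p_value


def apply_filters(
    columns: list[VariantColumn],
    reference: Genome,
    dropped_lcb_ids: set[int],
    n_genomes: int,
    config: FilterConfig,
) -> None:
    """Run all filters in place (REP, LCB, ALN, REC; QUAL is reserved)."""
    flag_repetitive(columns, reference, config.repeat_kmer)
    flag_lcb_size(columns, dropped_lcb_ids)
    flag_alignment_quality(columns, config.window_size, config.max_window_variants)
    phi_recombination(
        columns, n_genomes, config.phi_window, config.phi_permutations,
        config.phi_alpha, config.seed,
    )


# ---------------------------------------------------------------------------
# the filtered core SNP set
# ---------------------------------------------------------------------------

@dataclass
class SnpMatrix:
    """Retained core SNP columns: genome x column allele matrix."""

    genome_ids: list[str]
    columns: list[VariantColumn]

    @property
    def ref_positions(self) -> list[int]:
        return [v.ref_pos for v in self.columns]

    def row(self, gid: str) -> str:
        i = self.genome_ids.index(gid)
        return "".join(v.alleles[i] for v in self.columns)

    def __len__(self) -> int:
        return len(self.columns)


def core_snps(columns: list[VariantColumn], genome_ids: list[str]) -> SnpMatrix:
    """Columns with no flags, no indel allele and no N allele."""
    retained = [
        v for v in columns
        if not v.flags and not v.is_indel and "N" not in v.alleles
    ]
    if not retained:
        log.warning("no columns passed the core SNP filters")
    return SnpMatrix(genome_ids=list(genome_ids), columns=retained)
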