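"""End-to-end core-genome alignment pipeline.

Order of operations: MUMi recruitment -> multi-MUM search -> recursive
refinement -> LCB chaining -> weight filtering -> gap alignment ->
variant extraction and filtering -> SNP phylogeny.  Gap blocks are
independent units, so parallel alignment is bit-identical to serial.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass, field

import dendropy

from . import __version__
from .errors import NoCoreAlignmentError, SaturationError
from .gapalign import AlignedLCB, CoreAlignment, align_lcb, assemble_core_alignment
from .lcb import chain_lcbs, filter_lcbs
from .multimum import find_multimums, partitioned_multimums, recursive_refine
from .mumi import RecruitmentReport, recruit
from .phylogeny import nj_tree, snp_distances, tree_to_newick
from .sequence_io import Genome
from .variants import (
    FilterConfig,
    SnpMatrix,
    VariantColumn,
    apply_filters,
    core_snps,
    extract_columns,
)

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class RunConfig:
    """Every tunable of the pipeline; serialized into the archive."""

    min_anchor_length: int = 21
    refine_floor: int = 12
    max_gap: int = 10_000
    max_diag_diff: int = 100
    min_lcb_weight: int | None = None   # default 3 x min_anchor_length
    mumi_threshold: float = 0.3
    mumi_min_len: int = 19
    force_all: bool = False
    skip_recruitment: bool = False
    repeat_kmer: int = 21
    window_size: int = 100
    max_window_variants: int = 10
    phi_window: int = 1000
    phi_permutations: int = 1000
    phi_alpha: float = 0.05
    max_partition_size: int | None = None
    threads: int = 1
    seed: int = 42

    @property
    def effective_min_lcb_weight(self) -> int:
        if self.min_lcb_weight is not None:
            return self.min_lcb_weight
        return 3 * self.min_anchor_length

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


@dataclass
class AlignResult:
    """Everything the pipeline produces for one run."""

    config: RunConfig
    reference: Genome
    genomes: list[Genome]               # aligned genomes, reference first
    recruitment: RecruitmentReport | None
    core: CoreAlignment
    columns: list[VariantColumn]
    snps: SnpMatrix
    tree: dendropy.Tree | None
    tree_newick: str
    stats: dict = field(default_factory=dict)

    def lcb_boundaries(self, include_dropped: bool = True) -> list[int]:
        """Reference coordinates of LCB starts and ends.

        Weight-filtered blocks stay in the LCB table (their columns are
        flagged, not lost), so their boundaries count by default.
        """
        out = []
        for block in self.core.lcbs:
            if not include_dropped and not block.lcb.kept:
                continue
            lo, hi = block.lcb.ref_extent()
            out.extend((lo, hi))
        return sorted(out)


def run_align(
    genomes: list[Genome],
    reference: Genome | None = None,
    config: RunConfig | None = None,
) -> AlignResult:
    """Run the full pipeline on loaded genomes.

    ``genomes`` may include the reference; when ``reference`` is None the
    lexicographically first genome is used.
    """
    config = config or RunConfig()
    t0 = time.time()
    pool = sorted(genomes, key=lambda g: g.id)
    if reference is None:
        reference = pool[0]
    candidates = [g for g in pool if g.id != reference.id]
    if not candidates:
        raise NoCoreAlignmentError("core-genome alignment requires at least 2 genomes")

    recruitment = None
    if config.skip_recruitment:
        aligned_others = candidates
    else:
        recruitment = recruit(
            reference, candidates,
            threshold=config.mumi_threshold,
            force_all=config.force_all,
            min_len=config.mumi_min_len,
        )
        keep = set(recruitment.recruited_ids())
        aligned_others = [g for g in candidates if g.id in keep]
    aligned = [reference] + aligned_others
    genomes_by_id = {g.id: g for g in aligned}

    if config.max_partition_size and len(aligned_others) > config.max_partition_size:
        anchors = partitioned_multimums(
            aligned_others, reference, config.max_partition_size,
            config.min_anchor_length,
        )
    else:
        anchors = find_multimums(
            aligned_others, reference, config.min_anchor_length
        )
    if not anchors:
        raise NoCoreAlignmentError(
            f"no multi-MUM of length >= {config.min_anchor_length} shared "
            f"by all {len(aligned)} genomes"
        )
    log.info("initial multi-MUM search: %d anchors", len(anchors))

    anchors = recursive_refine(
        genomes_by_id, anchors,
        min_len=config.min_anchor_length,
        floor=config.refine_floor,
        max_gap=config.max_gap,
    )

    lcbs = chain_lcbs(
        anchors, max_gap=config.max_gap, max_diag_diff=config.max_diag_diff
    )
    kept, dropped = filter_lcbs(lcbs, config.effective_min_lcb_weight)

    blocks = _align_blocks(lcbs, genomes_by_id, config)
    core = assemble_core_alignment(blocks, genomes_by_id)

    columns = extract_columns(core)
    fconf = FilterConfig(
        repeat_kmer=config.repeat_kmer,
        window_size=config.window_size,
        max_window_variants=config.max_window_variants,
        min_lcb_weight=config.effective_min_lcb_weight,
        phi_window=config.phi_window,
        phi_permutations=config.phi_permutations,
        phi_alpha=config.phi_alpha,
        seed=config.seed,
    )
    apply_filters(
        columns, reference, {b.id for b in dropped}, len(aligned), fconf
    )
    snps = core_snps(columns, [g.id for g in aligned])

    tree = None
    newick = ""
    if len(snps) > 0:
        try:
            tree = nj_tree(snp_distances(snps))
            newick = tree_to_newick(tree)
        except SaturationError as exc:
            # per-SNP-site distances saturate when very few columns are
            # shared (e.g. two genomes differ at every retained column)
            log.warning("no tree built: %s", exc)
    else:
        log.warning("zero retained core SNPs: no tree built")

    stats = {
        "genomes": len(aligned),
        "anchors": len(anchors),
        "lcbs_kept": len(kept),
        "lcbs_dropped": len(dropped),
        "core_columns": core.core_columns,
        "variant_columns": len(columns),
        "core_snps": len(snps),
        "runtime_s": round(time.time() - t0, 2),
    }
    log.info("pipeline done: %s", stats)
    return AlignResult(
        config=config,
        reference=reference,
        genomes=aligned,
        recruitment=recruitment,
        core=core,
        columns=columns,
        snps=snps,
        tree=tree,
        tree_newick=newick,
        stats=stats,
    )


def _align_blocks(lcbs, genomes_by_id, config) -> list[AlignedLCB]:
    """Gap-align every LCB; parallel execution is bit-identical to
    serial because blocks are independent."""
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            return list(
                pool.map(lambda b: align_lcb(b, genomes_by_id, config.max_gap), lcbs)
            )
    return [align_lcb(b, genomes_by_id, config.max_gap) for b in lcbs]


def keyed_allele_matrix(result: AlignResult, gid: str) -> dict[int, dict[str, str]]:
    """Core SNP columns keyed to one genome's forward-strand coordinates.

    Used to verify that the choice of reference genome does not change
    the core SNP set: alleles are re-oriented to ``gid``'s forward
    strand, so runs with different references become directly comparable.
    """
    gi = result.snps.genome_ids.index(gid)
    orient = {b.lcb.id: b.lcb.orientation(gid) for b in result.core.lcbs}
    out: dict[int, dict[str, str]] = {}
    for v in result.snps.columns:
        pos = v.positions[gi]
        if pos is None:
            continue
        alleles = v.alleles
        if orient[v.lcb_id]:
            alleles = alleles.translate(_COMP)
        out[pos] = dict(zip(result.snps.genome_ids, alleles))
    return out
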