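"""Archive round-trips, corruption detection and format exports."""

import random

import pytest

from coremum.archive import (
    archive_from_result,
    bed_text,
    export,
    read_archive,
    reconstruct_msa,
    snp_fasta_text,
    vcf_text,
    write_archive,
    xmfa_from_result,
)
from coremum.errors import ArchiveError


@pytest.fixture(scope="module")
def stored(run8, tmp_path_factory):
    _, _, result = run8
    arch = archive_from_result(result)
    path = tmp_path_factory.mktemp("arch") / "run.cgar"
    write_archive(arch, path)
    return result, arch, path


def test_round_trip_identity(stored):
    _, arch, path = stored
    assert read_archive(path) == arch


def test_truncated_file_names_section(stored):
    _, _, path = stored
    data = path.read_bytes()
    short = path.parent / "short.cgar"
    short.write_bytes(data[: len(data) // 2])
    with pytest.raises(ArchiveError, match="section|truncated"):
        read_archive(short)


def test_bad_magic_rejected(stored, tmp_path):
    p = tmp_path / "x.cgar"
    p.write_bytes(b"NOPE" + b"\x00" * 32)
    with pytest.raises(ArchiveError, match="magic"):
        read_archive(p)


@pytest.mark.parametrize("trial", range(5))
def test_flipped_byte_detected(stored, tmp_path, trial):
    _, _, path = stored
    data = bytearray(path.read_bytes())
    rng = random.Random(trial)
    i = rng.randrange(24, len(data))
    data[i] ^= 0xFF
    p = tmp_path / f"flip{trial}.cgar"
    p.write_bytes(bytes(data))
    with pytest.raises(ArchiveError):
        read_archive(p)


def test_xmfa_reconstruction_bit_identical(stored):
    result, _, path = stored
    back = read_archive(path)
    assert reconstruct_msa(back, "xmfa") == xmfa_from_result(result)


def test_xmfa_rows_degap_to_genome_substrings(stored):
    result, arch, _ = stored
    from coremum.archive import _iter_blocks
    from coremum.sequence_io import revcomp

    gby = {g.id: g for g in result.genomes}
    for rec, rows in _iter_blocks(arch):
        for gi, gid in enumerate(arch.genome_ids):
            lo, hi = rec.extents[gi]
            expected = gby[gid].concat[lo:hi]
            if rec.orients[gi]:
                expected = revcomp(expected)
            assert rows[gid].replace("-", "") == expected


def test_maf_block_count_matches_kept_lcbs(stored):
    _, arch, _ = stored
    maf = reconstruct_msa(arch, "maf")
    kept = sum(1 for rec in arch.lcbs if rec.kept)
    assert maf.count("\na score=") == kept


def test_vcf_contract(stored, tmp_path):
    _, arch, _ = stored
    text = vcf_text(arch)
    records = [l for l in text.splitlines() if l and not l.startswith("#")]
    assert len(records) == len(arch.variants)
    # every record parses via cyvcf2 and sample count matches
    cyvcf2 = pytest.importorskip("cyvcf2")
    p = tmp_path / "out.vcf"
    p.write_text(text)
    vcf = cyvcf2.VCF(str(p))
    assert list(vcf.samples) == list(arch.genome_ids)
    parsed = list(vcf)
    assert len(parsed) == len(records)
    flagged = [v for v in arch.variants if v.flags]
    filtered = [r for r in parsed if r.FILTER is not None]
    assert len(filtered) == len(flagged)


def test_snp_fasta_dimensions(stored):
    _, arch, _ = stored
    text = snp_fasta_text(arch)
    rows = [l for l in text.splitlines() if l.startswith(">")]
    assert len(rows) == len(arch.genome_ids)
    retained = [
        v for v in arch.variants
        if not v.flags and "-" not in v.alleles and "N" not in v.alleles
    ]
    body = text.split(">")[1].splitlines()[1:]
    assert sum(len(l) for l in body) == len(retained)


def test_bed_has_one_region_per_kept_lcb(stored):
    _, arch, _ = stored
    lines = [l for l in bed_text(arch).splitlines() if l]
    kept = sum(1 for rec in arch.lcbs if rec.kept)
    # single-contig genomes: no clipping, exactly one record per block
    assert len(lines) == kept


def test_unknown_export_format_listed(stored, tmp_path):
    _, arch, _ = stored
    with pytest.raises(ValueError, match="snp_fasta"):
        export(arch, "parquet", tmp_path / "x")


def test_no_variants_archive_is_small(tmp_path):
    from coremum.pipeline import RunConfig, run_align
    from coremum.simulate import SimConfig, simulate_evolution

    genomes, _ = simulate_evolution(SimConfig(
        length=5000, leaves=4, rate=0.0, n_rearrangements=0, seed=1,
    ))
    result = run_align(genomes, config=RunConfig(
        seed=1, skip_recruitment=True, phi_permutations=100,
    ))
    arch = archive_from_result(result)
    assert arch.variants == []
    p = tmp_path / "empty.cgar"
    write_archive(arch, p)
    xmfa = xmfa_from_result(result)
    assert p.stat().st_size < 0.25 * len(xmfa)
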