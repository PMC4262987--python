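"""Reference-compressed binary archive of a core-genome alignment run.

One file holds the reference genome, annotations, the genome table, the
LCB table, every polymorphic column (packed 4 bits per genome), the SNP
tree and the full run configuration.  Monomorphic alignment content is
never stored: within an LCB every column is either an anchor column or
a gap column, and a column not recorded as polymorphic is by definition
identical to the reference base at that point, so the full gapped
alignment is exactly recoverable from reference + structure + variants.

Layout: a 16-byte header (magic ``CGAR``, version, endianness tag)
followed by length-prefixed, zlib-compressed, CRC-checked sections in
fixed order.  Integers are little-endian; variable-length integers use
LEB128 with zigzag for signed values.
"""

from __future__ import annotations

import hashlib
import json
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ArchiveError
from .sequence_io import SEP, Genome

MAGIC = b"CGAR"
VERSION = 1
SECTION_ORDER = [b"REFG", b"GNOM", b"ANNO", b"LCBS", b"VARS", b"TREE", b"CONF"]

_ALLELE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_ALLELE_CHAR = "ACGTN-"
_FLAG_BITS = {"REP": 1, "LCB": 2, "ALN": 4, "QUAL": 8, "REC": 16}
_BIT_FLAGS = {v: k for k, v in _FLAG_BITS.items()}


# ---------------------------------------------------------------------------
# varint helpers
# ---------------------------------------------------------------------------

def _write_uvarint(buf: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("uvarint must be non-negative")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def _zigzag(value: int) -> int:
    return (value << 1) ^ (value >> 63) if value < 0 else value << 1


def _write_svarint(buf: bytearray, value: int) -> None:
    _write_uvarint(buf, _zigzag(value))


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def uvarint(self) -> int:
        shift = 0
        result = 0
        while True:
            if self.pos >= len(self.data):
                raise ArchiveError("truncated varint")
            b = self.data[self.pos]
            self.pos += 1
            result |= (b & 0x7F) << shift
            if not b & 0x80:
                return result
            shift += 7

    def svarint(self) -> int:
        u = self.uvarint()
        return (u >> 1) ^ -(u & 1)

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ArchiveError("truncated payload")
        out = self.data[self.pos:self.pos + n]
        self.pos += n
        return out


# ---------------------------------------------------------------------------
# archive model
# ---------------------------------------------------------------------------

@dataclass
class LCBRecord:
    """Structure of one aligned block: segment layout + per-genome extents."""

    id: int
    kept: bool
    weight: int
    segments: list[tuple[int, int]]        # (kind 0=anchor 1=gap, length)
    extents: list[tuple[int, int]]         # per genome, genome-table order
    orients: list[bool]

    @property
    def ncols(self) -> int:
        return sum(length for _, length in self.segments)


@dataclass
class VariantRecord:
    lcb_id: int
    col: int
    ref_pos: int | None
    alleles: str
    flags: frozenset = field(default_factory=frozenset)

    @property
    def is_indel(self) -> bool:
        return "-" in self.alleles


@dataclass
class Archive:
    reference_id: str
    reference_contigs: list[tuple[str, str]]
    genome_ids: list[str]
    genome_table: list[dict]
    annotations: list[tuple]
    lcbs: list[LCBRecord]
    variants: list[VariantRecord]
    tree_newick: str
    config: dict
    version: int = VERSION

    def reference_genome(self) -> Genome:
        return Genome(id=self.reference_id, contigs=list(self.reference_contigs))


def archive_from_result(result, annotations=None) -> Archive:
    """Build the archive model from a pipeline result."""
    genome_ids = [g.id for g in result.genomes]
    genome_table = []
    for g in result.genomes:
        genome_table.append({
            "id": g.id,
            "nt_length": g.nt_length,
            "concat_length": g.concat_length,
            "contigs": [(n, len(s)) for n, s in g.contigs],
            "md5": hashlib.md5(g.concat.encode()).hexdigest(),
        })
    lcb_records = []
    for block in result.core.lcbs:
        lcb = block.lcb
        segments = []
        for kind, payload in block.segments:
            if kind == "anchor":
                segments.append((0, len(payload)))
            else:
                segments.append((1, payload.width))
        lcb_records.append(LCBRecord(
            id=lcb.id,
            kept=lcb.kept,
            weight=lcb.weight,
            segments=segments,
            extents=[lcb.extent(gid) for gid in genome_ids],
            orients=[lcb.orientation(gid) for gid in genome_ids],
        ))
    variants = [
        VariantRecord(
            lcb_id=v.lcb_id, col=v.col, ref_pos=v.ref_pos,
            alleles=v.alleles, flags=frozenset(v.flags),
        )
        for v in result.columns
    ]
    ann = list(annotations.intervals) if annotations is not None else []
    return Archive(
        reference_id=result.reference.id,
        reference_contigs=list(result.reference.contigs),
        genome_ids=genome_ids,
        genome_table=genome_table,
        annotations=ann,
        lcbs=lcb_records,
        variants=variants,
        tree_newick=result.tree_newick,
        config=result.config.to_dict(),
    )


# ---------------------------------------------------------------------------
# section codecs
# ---------------------------------------------------------------------------

def _sec_refg(a: Archive) -> bytes:
    head = json.dumps({
        "id": a.reference_id,
        "names": [n for n, _ in a.reference_contigs],
        "lengths": [len(s) for _, s in a.reference_contigs],
    }).encode()
    seq = "".join(s for _, s in a.reference_contigs).encode()
    return head + b"\x00" + seq


def _dec_refg(raw: bytes) -> tuple[str, list[tuple[str, str]]]:
    head, _, seq = raw.partition(b"\x00")
    meta = json.loads(head)
    text = seq.decode()
    contigs = []
    off = 0
    for name, length in zip(meta["names"], meta["lengths"]):
        contigs.append((name, text[off:off + length]))
        off += length
    return meta["id"], contigs


def _sec_lcbs(a: Archive) -> bytes:
    buf = bytearray()
    ng = len(a.genome_ids)
    _write_uvarint(buf, len(a.lcbs))
    _write_uvarint(buf, ng)
    for rec in a.lcbs:
        _write_uvarint(buf, rec.id)
        buf.append(1 if rec.kept else 0)
        _write_uvarint(buf, rec.weight)
        _write_uvarint(buf, len(rec.segments))
        for kind, length in rec.segments:
            _write_uvarint(buf, (length << 1) | kind)
    # starts as deltas vs the genome's previous block end; spans stored
    # directly for the reference, as deltas vs the reference span for
    # the rest (indel-free data compresses to near nothing)
    for gi in range(ng):
        prev_end = 0
        for rec in a.lcbs:
            start, end = rec.extents[gi]
            _write_svarint(buf, start - prev_end)
            if gi == 0:
                _write_uvarint(buf, end - start)
            else:
                ref_span = rec.extents[0][1] - rec.extents[0][0]
                _write_svarint(buf, (end - start) - ref_span)
            prev_end = end
    bits = bytearray((len(a.lcbs) * ng + 7) // 8)
    k = 0
    for gi in range(ng):
        for rec in a.lcbs:
            if rec.orients[gi]:
                bits[k >> 3] |= 1 << (k & 7)
            k += 1
    buf.extend(bits)
    return bytes(buf)


def _dec_lcbs(raw: bytes) -> list[LCBRecord]:
    r = _Reader(raw)
    n_lcbs = r.uvarint()
    ng = r.uvarint()
    lcbs: list[LCBRecord] = []
    for _ in range(n_lcbs):
        lcb_id = r.uvarint()
        kept = bool(r.take(1)[0])
        weight = r.uvarint()
        nseg = r.uvarint()
        segments = []
        for _ in range(nseg):
            v = r.uvarint()
            segments.append((v & 1, v >> 1))
        lcbs.append(LCBRecord(
            id=lcb_id, kept=kept, weight=weight, segments=segments,
            extents=[], orients=[],
        ))
    for gi in range(ng):
        prev_end = 0
        for rec in lcbs:
            start = prev_end + r.svarint()
            if gi == 0:
                span = r.uvarint()
            else:
                ref_span = rec.extents[0][1] - rec.extents[0][0]
                span = ref_span + r.svarint()
            rec.extents.append((start, start + span))
            prev_end = start + span
    bits = r.take((n_lcbs * ng + 7) // 8)
    k = 0
    for gi in range(ng):
        for rec in lcbs:
            rec.orients.append(bool(bits[k >> 3] & (1 << (k & 7))))
            k += 1
    return lcbs


def _sec_vars(a: Archive) -> bytes:
    buf = bytearray()
    ng = len(a.genome_ids)
    _write_uvarint(buf, len(a.variants))
    _write_uvarint(buf, ng)
    prev_lcb = 0
    prev_col = 0
    packed = bytearray()
    for v in a.variants:
        _write_uvarint(buf, v.lcb_id - prev_lcb)
        if v.lcb_id != prev_lcb:
            prev_col = 0
        _write_uvarint(buf, v.col - prev_col)
        prev_lcb, prev_col = v.lcb_id, v.col
        _write_uvarint(buf, 0 if v.ref_pos is None else v.ref_pos + 1)
        flags = 0
        for f in v.flags:
            flags |= _FLAG_BITS[f]
        buf.append(flags)
        for i in range(0, ng, 2):
            lo = _ALLELE_CODE[v.alleles[i]]
            hi = _ALLELE_CODE[v.alleles[i + 1]] if i + 1 < ng else 0
            packed.append(lo | (hi << 4))
    buf.extend(packed)
    return bytes(buf)


def _dec_vars(raw: bytes) -> list[VariantRecord]:
    r = _Reader(raw)
    n = r.uvarint()
    ng = r.uvarint()
    heads = []
    prev_lcb = 0
    prev_col = 0
    for _ in range(n):
        dl = r.uvarint()
        lcb_id = prev_lcb + dl
        if dl:
            prev_col = 0
        col = prev_col + r.uvarint()
        prev_lcb, prev_col = lcb_id, col
        rp = r.uvarint()
        ref_pos = None if rp == 0 else rp - 1
        fl = r.take(1)[0]
        flags = frozenset(name for bit, name in _BIT_FLAGS.items() if fl & bit)
        heads.append((lcb_id, col, ref_pos, flags))
    per_col = (ng + 1) // 2
    out = []
    for lcb_id, col, ref_pos, flags in heads:
        data = r.take(per_col)
        alleles = []
        for i in range(ng):
            b = data[i >> 1]
            code = (b >> 4) if i & 1 else (b & 0x0F)
            alleles.append(_ALLELE_CHAR[code])
        out.append(VariantRecord(
            lcb_id=lcb_id, col=col, ref_pos=ref_pos,
            alleles="".join(alleles), flags=flags,
        ))
    return out


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def write_archive(archive: Archive, path: str | Path) -> None:
    """Serialize to the chunked binary layout (zlib + CRC per section)."""
    sections = {
        b"REFG": _sec_refg(archive),
        b"GNOM": json.dumps(archive.genome_table).encode(),
        b"ANNO": json.dumps(archive.annotations).encode(),
        b"LCBS": _sec_lcbs(archive),
        b"VARS": _sec_vars(archive),
        b"TREE": archive.tree_newick.encode(),
        b"CONF": json.dumps(archive.config, sort_keys=True).encode(),
    }
    with open(path, "wb") as out:
        out.write(MAGIC + struct.pack("<HB", archive.version, 1) + b"\x00" * 9)
        for tag in SECTION_ORDER:
            raw = sections[tag]
            comp = zlib.compress(raw, 6)
            out.write(tag)
            out.write(struct.pack("<IQQ", zlib.crc32(comp), len(raw), len(comp)))
            out.write(comp)


def read_archive(path: str | Path) -> Archive:
    """Read and verify an archive; corruption fails naming the section."""
    data = Path(path).read_bytes()
    if len(data) < 16 or data[:4] != MAGIC:
        raise ArchiveError(f"{path}: not a coremum archive (bad magic)")
    version, _endian = struct.unpack("<HB", data[4:7])
    if version != VERSION:
        raise ArchiveError(
            f"{path}: unsupported archive version {version} (expected {VERSION})"
        )
    pos = 16
    sections: dict[bytes, bytes] = {}
    for tag in SECTION_ORDER:
        name = tag.decode()
        if pos + 24 > len(data):
            raise ArchiveError(f"{path}: truncated before section {name}")
        if data[pos:pos + 4] != tag:
            raise ArchiveError(f"{path}: expected section {name}")
        crc, raw_len, comp_len = struct.unpack("<IQQ", data[pos + 4:pos + 24])
        pos += 24
        if pos + comp_len > len(data):
            raise ArchiveError(f"{path}: truncated payload in section {name}")
        comp = data[pos:pos + comp_len]
        pos += comp_len
        if zlib.crc32(comp) != crc:
            raise ArchiveError(f"{path}: checksum mismatch in section {name}")
        try:
            raw = zlib.decompress(comp)
        except zlib.error as exc:
            raise ArchiveError(f"{path}: corrupt section {name}: {exc}") from exc
        if len(raw) != raw_len:
            raise ArchiveError(f"{path}: length mismatch in section {name}")
        sections[tag] = raw

    ref_id, contigs = _dec_refg(sections[b"REFG"])
    genome_table = json.loads(sections[b"GNOM"])
    annotations = [tuple(iv) for iv in json.loads(sections[b"ANNO"])]
    lcbs = _dec_lcbs(sections[b"LCBS"])
    variants = _dec_vars(sections[b"VARS"])
    genome_table = [
        {**g, "contigs": [tuple(c) for c in g["contigs"]]} for g in genome_table
    ]
    return Archive(
        reference_id=ref_id,
        reference_contigs=contigs,
        genome_ids=[g["id"] for g in genome_table],
        genome_table=genome_table,
        annotations=annotations,
        lcbs=lcbs,
        variants=variants,
        tree_newick=sections[b"TREE"].decode(),
        config=json.loads(sections[b"CONF"]),
        version=version,
    )


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def reconstruct_rows(archive: Archive, rec: LCBRecord) -> dict[str, str]:
    """Rebuild the full gapped rows of one LCB from reference + variants."""
    ref_concat = SEP.join(s for _, s in archive.reference_contigs)
    by_col = {
        v.col: v for v in archive.variants if v.lcb_id == rec.id
    }
    return _rows_from_structure(archive.genome_ids, ref_concat, rec, by_col)


def _rows_from_structure(genome_ids, ref_concat, rec, by_col) -> dict[str, str]:
    ng = len(genome_ids)
    ref_ptr = rec.extents[0][0]
    rows = [[] for _ in range(ng)]
    col = 0
    for kind, length in rec.segments:
        if kind == 0:
            text = ref_concat[ref_ptr:ref_ptr + length]
            for r in rows:
                r.append(text)
            ref_ptr += length
            col += length
            continue
        for _ in range(length):
            v = by_col.get(col)
            if v is None:
                c = ref_concat[ref_ptr]
                if c == SEP:
                    c = "N"
                for r in rows:
                    r.append(c)
                ref_ptr += 1
            else:
                for i, r in enumerate(rows):
                    r.append(v.alleles[i])
                if v.alleles[0] != "-":
                    ref_ptr += 1
            col += 1
    return {gid: "".join(parts) for gid, parts in zip(genome_ids, rows)}


def _iter_blocks(archive: Archive, kept_only: bool = True):
    ref_concat = SEP.join(s for _, s in archive.reference_contigs)
    variants_by_lcb: dict[int, dict[int, VariantRecord]] = {}
    for v in archive.variants:
        variants_by_lcb.setdefault(v.lcb_id, {})[v.col] = v
    for rec in archive.lcbs:
        if kept_only and not rec.kept:
            continue
        rows = _rows_from_structure(
            archive.genome_ids, ref_concat, rec, variants_by_lcb.get(rec.id, {})
        )
        yield rec, rows


def blocks_from_result(result, kept_only: bool = True):
    """Adapt a live pipeline result to the block interface the text
    writers consume (so direct and archive-reconstructed exports share
    one code path)."""
    genome_ids = [g.id for g in result.genomes]
    for block in result.core.lcbs:
        if kept_only and not block.lcb.kept:
            continue
        rec = LCBRecord(
            id=block.lcb.id,
            kept=block.lcb.kept,
            weight=block.lcb.weight,
            segments=[],
            extents=[block.lcb.extent(g) for g in genome_ids],
            orients=[block.lcb.orientation(g) for g in genome_ids],
        )
        yield rec, {gid: block.row(gid) for gid in genome_ids}


def xmfa_from_result(result) -> str:
    """XMFA written directly from the in-memory core alignment."""
    return xmfa_text([g.id for g in result.genomes], blocks_from_result(result))


# ---------------------------------------------------------------------------
# text exporters
# ---------------------------------------------------------------------------

def xmfa_text(genome_ids: list[str], blocks) -> str:
    """XMFA with one alignment block per LCB; 1-based inclusive
    coordinates on each genome's forward strand, strand signs per row."""
    out = ["#FormatVersion coremum/1"]
    for i, gid in enumerate(genome_ids, start=1):
        out.append(f"#Sequence{i}Entry\t{gid}")
    for rec, rows in blocks:
        for i, gid in enumerate(genome_ids):
            start, end = rec.extents[i]
            strand = "-" if rec.orients[i] else "+"
            out.append(f"> {i + 1}:{start + 1}-{end} {strand} {gid}")
            row = rows[gid]
            for k in range(0, len(row), 80):
                out.append(row[k:k + 80])
        out.append("=")
    return "\n".join(out) + "\n"


def maf_text(genome_ids: list[str], blocks, src_sizes: dict[str, int]) -> str:
    """MAF with 0-based starts on the aligned strand."""
    out = ["##maf version=1 program=coremum", ""]
    for rec, rows in blocks:
        out.append("a score=0")
        for i, gid in enumerate(genome_ids):
            start, end = rec.extents[i]
            size = end - start
            src_size = src_sizes[gid]
            if rec.orients[i]:
                strand = "-"
                s = src_size - end
            else:
                strand = "+"
                s = start
            out.append(
                f"s {gid} {s} {size} {strand} {src_size} {rows[gid]}"
            )
        out.append("")
    return "\n".join(out) + "\n"


def reconstruct_msa(archive: Archive, fmt: str = "xmfa") -> str:
    """Rebuild the core alignment text (XMFA or MAF) from the archive."""
    if fmt == "xmfa":
        return xmfa_text(archive.genome_ids, _iter_blocks(archive))
    if fmt == "maf":
        sizes = {g["id"]: g["concat_length"] for g in archive.genome_table}
        return maf_text(archive.genome_ids, _iter_blocks(archive), sizes)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _contig_lookup(archive: Archive):
    """Map reference concat position -> (contig name, 1-based offset)."""
    bounds = []
    off = 0
    for name, seq in archive.reference_contigs:
        bounds.append((off, off + len(seq), name))
        off += len(seq) + 1
    def lookup(pos: int) -> tuple[str, int]:
        for lo, hi, name in bounds:
            if lo <= pos < hi:
                return name, pos - lo + 1
        raise ArchiveError(f"reference position {pos} is a contig separator")
    return lookup


def vcf_text(archive: Archive) -> str:
    """One record per variant column; FILTER is PASS or the joined flags."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=coremum",
    ]
    for name, seq in archive.reference_contigs:
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    for flag, desc in (
        ("REP", "repetitive reference sequence"),
        ("LCB", "block below the LCB weight threshold"),
        ("ALN", "dense variant window (possible misalignment)"),
        ("QUAL", "poor base quality (reserved, never set)"),
        ("REC", "recombination signal (PHI test)"),
    ):
        lines.append(f'##FILTER=<ID={flag},Description="{desc}">')
    lines.append('##INFO=<ID=LCB,Number=1,Type=Integer,Description="LCB id">')
    lines.append('##INFO=<ID=COL,Number=1,Type=Integer,Description="column in LCB">')
    lines.append('##ALT=<ID=INS,Description="insertion relative to the reference">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="haploid allele index">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(archive.genome_ids)
    )
    lookup = _contig_lookup(archive)
    # ref position for reference-gap columns: nearest preceding ref base
    prev_pos_by_lcb: dict[int, int] = {
        rec.id: rec.extents[0][0] for rec in archive.lcbs
    }
    records = []
    last_ref_pos: dict[int, int] = dict(prev_pos_by_lcb)
    for v in sorted(archive.variants, key=lambda v: (v.lcb_id, v.col)):
        if v.ref_pos is not None:
            last_ref_pos[v.lcb_id] = v.ref_pos
            pos = v.ref_pos
            symbolic = False
        else:
            pos = last_ref_pos.get(v.lcb_id, 0)
            symbolic = True
        records.append((pos, v, symbolic))
    records.sort(key=lambda t: (t[0], t[1].lcb_id, t[1].col))
    for pos, v, symbolic in records:
        try:
            chrom, pos1 = lookup(pos)
        except ArchiveError:
            continue
        if symbolic:
            ref_allele = _ref_base(archive, pos)
            alts = ["<INS>"]
            allele_index = {}
        else:
            ref_allele = v.alleles[0]
            alts = sorted(
                {("*" if a == "-" else a) for a in v.alleles}
                - {ref_allele, "N"}
            )
            allele_index = {a: i + 1 for i, a in enumerate(alts)}
        filt = "PASS" if not v.flags else ";".join(sorted(v.flags))
        gts = []
        for a in v.alleles:
            if symbolic:
                gts.append("." if a == "-" else "1")
            elif a == "N":
                gts.append(".")
            elif a == ref_allele:
                gts.append("0")
            else:
                gts.append(str(allele_index["*" if a == "-" else a]))
        lines.append(
            f"{chrom}\t{pos1}\t.\t{ref_allele}\t{','.join(alts) or '.'}\t.\t"
            f"{filt}\tLCB={v.lcb_id};COL={v.col}\tGT\t" + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


def _ref_base(archive: Archive, pos: int) -> str:
    off = 0
    for _name, seq in archive.reference_contigs:
        if pos < off + len(seq):
            return seq[pos - off]
        off += len(seq) + 1
    return "N"


def snp_fasta_text(archive: Archive) -> str:
    """Concatenated retained-SNP alleles per genome (the tree input)."""
    retained = [
        v for v in archive.variants
        if not v.flags and "-" not in v.alleles and "N" not in v.alleles
    ]
    out = []
    for i, gid in enumerate(archive.genome_ids):
        out.append(f">{gid}")
        row = "".join(v.alleles[i] for v in retained)
        for k in range(0, len(row), 70):
            out.append(row[k:k + 70])
        if not row:
            out.append("")
    return "\n".join(out) + "\n"


def bed_text(archive: Archive) -> str:
    """Kept LCBs as BED on reference contig coordinates (score=weight,
    clipped at contig boundaries)."""
    bounds = []
    off = 0
    for name, seq in archive.reference_contigs:
        bounds.append((off, off + len(seq), name))
        off += len(seq) + 1
    lines = []
    for rec in archive.lcbs:
        if not rec.kept:
            continue
        lo, hi = rec.extents[0]
        for c_lo, c_hi, name in bounds:
            s = max(lo, c_lo)
            e = min(hi, c_hi)
            if s < e:
                score = min(1000, rec.weight)
                lines.append(
                    f"{name}\t{s - c_lo}\t{e - c_lo}\tLCB{rec.id}\t{score}\t+"
                )
    return "\n".join(lines) + "\n"


EXPORT_FORMATS = ("vcf", "xmfa", "maf", "snp_fasta", "newick", "bed")


def export(archive: Archive, fmt: str, path: str | Path) -> None:
    """Write one of the supported text exports."""
    if fmt == "vcf":
        text = vcf_text(archive)
    elif fmt in ("xmfa", "maf"):
        text = reconstruct_msa(archive, fmt)
    elif fmt == "snp_fasta":
        text = snp_fasta_text(archive)
    elif fmt == "newick":
        text = archive.tree_newick
    elif fmt == "bed":
        text = bed_text(archive)
    else:
        raise ValueError(
            f"unknown export format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}"
        )
    Path(path).write_text(text)
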