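"""Reading and writing genome sequences and annotations.

A :class:`Genome` holds the contigs of one assembly together with a single
concatenated coordinate system.  Contigs are joined by a separator
character that never matches a nucleotide, so exact matches can never
cross a contig boundary.  All internal coordinates are 0-based half-open;
conversion to 1-based happens only in exporters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .errors import InputFormatError

log = logging.getLogger(__name__)

#: contig separator used inside the concatenated coordinate system.  One
#: character per junction; the suffix-index encoder additionally makes
#: every separator occurrence globally unique so separators never take
#: part in any exact match.
SEP = "\x1f"

_COMPLEMENT = str.maketrans("ACGTN" + SEP, "TGCAN" + SEP)
_VALID = set("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N, separators map to themselves."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and map every character outside {A,C,G,T} to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


@dataclass
class Genome:
    """One input assembly: contigs plus a concatenated coordinate system."""

    id: str
    contigs: list[tuple[str, str]]
    offsets: list[int] = field(init=False, repr=False)
    _concat: str = field(init=False, repr=False, default="")

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise InputFormatError(
                f"genome {self.id!r}: duplicate contig names"
            )
        self._concat = SEP.join(seq for _, seq in self.contigs)
        self.offsets = []
        pos = 0
        for _, seq in self.contigs:
            self.offsets.append(pos)
            pos += len(seq) + 1  # +1 for the separator after the contig

    @property
    def concat(self) -> str:
        """Concatenated sequence with one separator between contigs."""
        return self._concat

    @property
    def concat_length(self) -> int:
        return len(self._concat)

    @property
    def nt_length(self) -> int:
        """Total nucleotide length (separators excluded)."""
        return sum(len(seq) for _, seq in self.contigs)

    def contig_names(self) -> list[str]:
        return [n for n, _ in self.contigs]


def global_to_contig(genome: Genome, pos: int) -> tuple[str, int] | None:
    """Map a concatenated position back to (contig name, offset).

    Returns None for separator positions.  Raises IndexError when out of
    range.
    """
    if pos < 0 or pos >= genome.concat_length:
        raise IndexError(
            f"position {pos} out of range for genome {genome.id!r} "
            f"(concat length {genome.concat_length})"
        )
    lo, hi = 0, len(genome.offsets) - 1
    while lo < hi:  # rightmost offset <= pos
        mid = (lo + hi + 1) // 2
        if genome.offsets[mid] <= pos:
            lo = mid
        else:
            hi = mid - 1
    name, seq = genome.contigs[lo]
    off = pos - genome.offsets[lo]
    if off >= len(seq):
        return None  # separator
    return name, off


def contig_to_global(genome: Genome, contig: str, offset: int) -> int:
    """Inverse of :func:`global_to_contig`."""
    for i, (name, seq) in enumerate(genome.contigs):
        if name == contig:
            if offset < 0 or offset >= len(seq):
                raise IndexError(
                    f"offset {offset} out of range for contig {contig!r}"
                )
            return genome.offsets[i] + offset
    raise KeyError(f"unknown contig {contig!r} in genome {genome.id!r}")


def load_genome(path: str | Path, genome_id: str | None = None) -> Genome:
    """Load one MultiFASTA assembly.

    Sequences are uppercased; characters outside {A,C,G,T} become N.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.name
        for suffix in (".gz", ".fa", ".fasta", ".fna", ".mfa"):
            if genome_id.endswith(suffix):
                genome_id = genome_id[: -len(suffix)]
    contigs: list[tuple[str, str]] = []
    try:
        with open(path) as handle:
            for record in SeqIO.parse(handle, "fasta"):
                seq = normalize(str(record.seq))
                if not seq:
                    continue
                contigs.append((record.id, seq))
    except (OSError, ValueError) as exc:
        raise InputFormatError(f"cannot read FASTA file {path}: {exc}") from exc
    if not contigs:
        raise InputFormatError(f"no FASTA records with sequence in {path}")
    genome = Genome(id=genome_id, contigs=contigs)
    log.info(
        "loaded %s: %d contig(s), %d bp", genome.id, len(contigs),
        genome.nt_length,
    )
    return genome


_FASTA_SUFFIXES = (".fa", ".fasta", ".fna", ".mfa")


def load_genome_dir(path: str | Path, reference: Genome | None = None) -> list[Genome]:
    """Load every FASTA file in a directory, ordered lexicographically.

    The reference (if loaded separately) counts toward the minimum of two
    genomes required for a core-genome alignment.
    """
    path = Path(path)
    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in _FASTA_SUFFIXES
    )
    genomes = [load_genome(p) for p in files]
    if reference is not None:
        before = len(genomes)
        genomes = [g for g in genomes if g.id != reference.id]
        if len(genomes) < before:
            log.info(
                "%s: skipping %d file(s) matching the reference id %r",
                path, before - len(genomes), reference.id,
            )
    ids = [g.id for g in genomes] + ([reference.id] if reference else [])
    if len(set(ids)) != len(ids):
        raise InputFormatError(f"duplicate genome ids in {path}: {sorted(ids)}")
    total = len(genomes) + (1 if reference is not None else 0)
    if total < 2:
        raise InputFormatError(
            "core-genome alignment requires at least 2 genomes"
        )
    return genomes


@dataclass
class AnnotationSet:
    """Reference annotation intervals, 0-based half-open internally."""

    intervals: list[tuple[str, int, int, str, str, str]]
    # (contig, start, end, strand, feature_type, label)
    skipped: int = 0

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int, str, str, str]]:
        return iter(self.intervals)


def load_annotations(
    path: str | Path,
    fmt: str,
    reference: Genome | None = None,
) -> AnnotationSet:
    """Read annotations from BED (native 0-based half-open) or GenBank
    (1-based inclusive, converted on input).

    Intervals referencing a contig absent from the reference are skipped
    with a warning and counted in ``skipped``.
    """
    path = Path(path)
    known = set(reference.contig_names()) if reference is not None else None
    intervals: list[tuple[str, int, int, str, str, str]] = []
    skipped = 0

    def _admit(contig, start, end, strand, ftype, label):
        nonlocal skipped
        if start >= end:
            raise InputFormatError(
                f"{path}: interval {contig}:{start}-{end} has start >= end"
            )
        if known is not None and contig not in known:
            log.warning("%s: skipping interval on unknown contig %r", path, contig)
            skipped += 1
            return
        intervals.append((contig, start, end, strand, ftype, label))

    if fmt == "bed":
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise InputFormatError(f"{path}: malformed BED line {line!r}")
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
                label = parts[3] if len(parts) > 3 else ""
                strand = parts[5] if len(parts) > 5 else "+"
                _admit(contig, start, end, strand, "region", label)
    elif fmt == "genbank":
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except ValueError as exc:
            raise InputFormatError(f"cannot parse GenBank file {path}: {exc}") from exc
        for record in records:
            for feat in record.features:
                if feat.type == "source":
                    continue
                start = int(feat.location.start)  # biopython is 0-based
                end = int(feat.location.end)
                strand = "-" if feat.location.strand == -1 else "+"
                label = feat.qualifiers.get(
                    "locus_tag", feat.qualifiers.get("gene", [""])
                )[0]
                _admit(record.id, start, end, strand, feat.type, label)
    else:
        raise InputFormatError(f"unknown annotation format {fmt!r}")

    log.info("%s: %d annotation interval(s), %d skipped", path, len(intervals), skipped)
    return AnnotationSet(intervals=intervals, skipped=skipped)


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    """Write (name, sequence) records as FASTA."""
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")
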