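"""Reading and writing the text formats the pipeline touches.

FASTQ (4-line), SAM text records, FASTA, BED intervals and CIGAR strings.

Coordinate conventions used throughout the package:

* BED intervals are 0-based half-open (``start`` inclusive, ``end`` exclusive).
* SAM/alignment positions are 1-based inclusive, as in the SAM standard.

Sequences are upper-cased on ingest and restricted to the A/C/G/T/N alphabet;
``N`` never counts as a match anywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "ReadRecord",
    "AlignmentRecord",
    "GenomicInterval",
    "CigarInfo",
    "read_fastq",
    "write_fastq",
    "collate_pairs",
    "parse_cigar",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_sam",
    "write_sam",
]

VALID_BASES = frozenset("ACGTN")

_PAIR_SUFFIX = re.compile(r"/([12])$")


class FormatError(ValueError):
    """Raised when an input file violates its format or a record invariant."""


# ---------------------------------------------------------------------------
# Reads


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: name, nucleotide sequence and per-base qualities.

    ``pair_member`` is ``"first"``/``"second"`` for paired-end mates (derived
    from a ``/1``/``/2`` name suffix or SAM flags) and ``"none"`` otherwise.
    """

    name: str
    sequence: str
    qualities: str
    pair_member: str = "none"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FormatError(f"read {self.name!r}: empty sequence")
        if len(seq) != len(self.qualities):
            raise FormatError(
                f"read {self.name!r}: sequence length {len(seq)} != "
                f"quality length {len(self.qualities)}"
            )
        if set(seq) - VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise FormatError(f"read {self.name!r}: invalid bases {bad}")
        if self.pair_member not in ("none", "first", "second"):
            raise FormatError(f"read {self.name!r}: bad pair_member {self.pair_member!r}")

    @property
    def base_name(self) -> str:
        """Name with any trailing ``/1`` or ``/2`` mate suffix removed."""
        return _PAIR_SUFFIX.sub("", self.name)


def _pair_member_from_name(name: str) -> str:
    m = _PAIR_SUFFIX.search(name)
    if m is None:
        return "none"
    return "first" if m.group(1) == "1" else "second"


def read_fastq(stream: Union[str, Path, IO[str]]) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects from a 4-line FASTQ stream in file order.

    Raises :class:`FormatError` naming the record index for truncated records
    and the read name for sequence/quality length mismatches.
    """
    handle = open(stream) if isinstance(stream, (str, Path)) else stream
    try:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"FASTQ record {index}: {exc}") from exc
            name = title.split()[0]
            try:
                yield ReadRecord(name, seq, qual, _pair_member_from_name(name))
            except FormatError as exc:
                raise FormatError(f"FASTQ record {index}: {exc}") from exc
            index += 1
    finally:
        if isinstance(stream, (str, Path)):
            handle.close()


def write_fastq(records: Iterable[ReadRecord], stream: Union[str, Path, IO[str]]) -> int:
    """Write records as 4-line FASTQ; returns the number of records written."""
    handle = open(stream, "w") if isinstance(stream, (str, Path)) else stream
    n = 0
    try:
        for rec in records:
            handle.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.qualities}\n")
            n += 1
    finally:
        if isinstance(stream, (str, Path)):
            handle.close()
    return n


def collate_pairs(records: Iterable[ReadRecord]) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Pair up adjacent records with identical base names (mate suffixes ignored).

    Input must be name-collated, i.e. each mate pair adjacent. A record whose
    successor has a different base name raises :class:`FormatError` reporting
    the orphan.
    """
    pending: Optional[ReadRecord] = None
    for rec in records:
        if pending is None:
            pending = rec
            continue
        if pending.base_name == rec.base_name:
            yield pending, rec
            pending = None
        else:
            raise FormatError(f"orphan read {pending.name!r}: next record is {rec.name!r}")
    if pending is not None:
        raise FormatError(f"orphan read {pending.name!r} at end of input")


# ---------------------------------------------------------------------------
# CIGAR

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("MIS=X")
_MATCH_OPS = frozenset("M=")


@dataclass(frozen=True)
class CigarInfo:
    """Parsed CIGAR: ordered operations plus derived query-level quantities.

    ``query_length`` sums the query-consuming operations M/I/S/=/X (hard clips
    excluded). ``match_fraction`` is the fraction of the query under M or ``=``
    (X counts toward the denominator only). Both are ``None`` for the
    undefined CIGAR ``"*"``.
    """

    operations: Optional[tuple[tuple[str, int], ...]]
    query_length: Optional[int]
    match_fraction: Optional[float]

    @property
    def is_undefined(self) -> bool:
        return self.operations is None


def parse_cigar(cigar_text: str) -> CigarInfo:
    """Parse a SAM CIGAR string; ``"*"`` yields an explicit undefined marker."""
    if cigar_text == "*":
        return CigarInfo(None, None, None)
    if not cigar_text:
        raise FormatError("empty CIGAR string")
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar_text):
        if m.start() != pos:
            raise FormatError(f"malformed CIGAR {cigar_text!r} at offset {pos}")
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(cigar_text):
        raise FormatError(f"malformed CIGAR {cigar_text!r} at offset {pos}")
    qlen = sum(n for op, n in ops if op in _QUERY_OPS)
    if qlen == 0:
        raise FormatError(f"CIGAR {cigar_text!r} consumes no query bases")
    matched = sum(n for op, n in ops if op in _MATCH_OPS)
    return CigarInfo(tuple(ops), qlen, matched / qlen)


# ---------------------------------------------------------------------------
# Alignments

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_FIRST = 0x40
_FLAG_SECOND = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignmentRecord:
    """A mapped (or unmapped) read with SAM-style position, CIGAR and flags.

    ``position`` is the 1-based leftmost mapped base; unmapped records carry
    ``reference_name=None`` and ``position=0``. The stored sequence follows the
    SAM convention (reverse-strand alignments store the reverse complement of
    the original read).
    """

    read: ReadRecord
    reference_name: Optional[str]
    position: int
    cigar: str
    mapq: int
    flag: int = 0
    # mate placement, used when emitting paired SAM
    mate_reference_name: Optional[str] = None
    mate_position: int = 0
    template_length: int = 0

    def __post_init__(self) -> None:
        if self.is_unmapped:
            return
        if self.position < 1:
            raise FormatError(f"mapped record {self.read.name!r}: position {self.position} < 1")
        info = parse_cigar(self.cigar)
        if not info.is_undefined and info.query_length != len(self.read.sequence):
            raise FormatError(
                f"record {self.read.name!r}: CIGAR consumes {info.query_length} "
                f"bases but sequence has {len(self.read.sequence)}"
            )

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & _FLAG_UNMAPPED)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & _FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & _FLAG_PROPER)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & _FLAG_REVERSE)

    @property
    def is_first_in_pair(self) -> bool:
        return bool(self.flag & _FLAG_FIRST)

    @property
    def is_second_in_pair(self) -> bool:
        return bool(self.flag & _FLAG_SECOND)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & _FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & _FLAG_SUPPLEMENTARY)

    @property
    def cigar_info(self) -> CigarInfo:
        return parse_cigar(self.cigar)

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost mapped base (reference-consuming ops)."""
        if self.is_unmapped:
            return 0
        info = parse_cigar(self.cigar)
        if info.is_undefined:
            return self.position
        ref_len = sum(n for op, n in info.operations if op in "MDN=X")
        return self.position + ref_len - 1


def read_sam(path: Union[str, Path]) -> Iterator[AlignmentRecord]:
    """Yield :class:`AlignmentRecord` objects from a SAM text file in file order."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            seq = aln.query_sequence
            if seq is None:
                continue  # sequence-less records carry nothing to screen
            if aln.query_qualities is not None:
                qual = pysam.qualities_to_qualitystring(aln.query_qualities)
            else:
                qual = "I" * len(seq)
            pair = "none"
            if aln.is_paired:
                pair = "first" if aln.is_read1 else "second"
            read = ReadRecord(aln.query_name, seq, qual, pair)
            yield AlignmentRecord(
                read=read,
                reference_name=None if aln.is_unmapped else aln.reference_name,
                position=0 if aln.is_unmapped else aln.reference_start + 1,
                cigar=aln.cigarstring or "*",
                mapq=aln.mapping_quality,
                flag=aln.flag,
                mate_reference_name=(
                    None if aln.mate_is_unmapped or not aln.is_paired else aln.next_reference_name
                ),
                mate_position=0 if aln.mate_is_unmapped else aln.next_reference_start + 1,
                template_length=aln.template_length,
            )


def write_sam(
    records: Iterable[AlignmentRecord],
    path: Union[str, Path],
    references: dict[str, int],
) -> int:
    """Write records as SAM text with an @SQ header built from ``references``."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        }
    )
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read.base_name
            seg.flag = rec.flag
            seg.mapping_quality = rec.mapq
            seg.query_sequence = rec.read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(rec.read.qualities)
            if rec.is_unmapped:
                seg.reference_id = -1
                seg.reference_start = -1
            else:
                seg.reference_id = header.get_tid(rec.reference_name)
                seg.reference_start = rec.position - 1
                seg.cigarstring = rec.cigar
            if rec.mate_reference_name is not None:
                seg.next_reference_id = header.get_tid(rec.mate_reference_name)
                seg.next_reference_start = rec.mate_position - 1
                seg.template_length = rec.template_length
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            out.write(seg)
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict (upper-cased)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in BED convention: 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end}: requires 0 <= start < end"
            )

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Minimum gap between two intervals (0 if overlapping; None across chroms)."""
        if self.chrom != other.chrom:
            return None
        if self.end <= other.start:
            return other.start - self.end
        if other.end <= self.start:
            return self.start - other.end
        return 0


_BED_HEADER = "# bed: chrom\tstart\tend\tname\tscore\tflag (0-based half-open coordinates)"


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: Union[str, Path],
    flags: Optional[Sequence[str]] = None,
) -> None:
    """Write intervals as BED6-style text: chrom, start, end, name, score, flag.

    The score column carries the supporting-read count for integration calls;
    ``flags`` (optional, one per interval) fills the sixth column, ``"."``
    otherwise. Intervals are validated (start < end) before any line is written.
    """
    if flags is not None and len(flags) != len(intervals):
        raise ValueError("flags must align one-to-one with intervals")
    rows = []
    for i, iv in enumerate(intervals):
        flag = flags[i] if flags is not None else "."
        rows.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{_format_score(iv.score)}\t{flag}")
    with open(path, "w") as handle:
        handle.write(_BED_HEADER + "\n")
        for row in rows:
            handle.write(row + "\n")


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Read a BED file (comment lines ignored) into intervals.

    Columns beyond the fifth are ignored; missing name/score default to
    ``"."``/0.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has {len(fields)} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0
            intervals.append(GenomicInterval(fields[0], start, end, name, score))
    return intervals


def read_bed_flags(path: Union[str, Path]) -> list[str]:
    """Sixth-column flags of a BED file written by :func:`write_bed`."""
    flags = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            flags.append(fields[5] if len(fields) > 5 else ".")
    return flags
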