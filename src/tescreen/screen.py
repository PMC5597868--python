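"""Chimeric-read detection, trimming and mate retrieval.

A read is *chimeric* when it carries at least ``min_match_len`` bases of a
bait (a TE/virus edge probe) at identity ``min_identity`` or better. Detection
combines two placement routes per bait: the optimal Smith–Waterman local
alignment (tolerates indels) and an exhaustive ungapped scan of the bait over
the read (tolerates mismatches at the outermost bait positions, which a local
optimum would trim off, and allows partial bait overhang at the read ends).
The best passing placement wins; ties resolve by score, then fixed bait order,
then the gapped route.

Identity is counted over aligned *bait* positions (matches / bait span), so a
20-bp bait at 90 % identity admits up to two mismatches.

The screening of a library emits three FASTQ files (host-flank trimmed reads,
their mates, the removed TE portions) and a tab-delimited chimera report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from . import _sw
from .baits import BAIT_KEYS, BaitSet
from .formats import (
    AlignmentRecord,
    FormatError,
    ReadRecord,
    collate_pairs,
    parse_cigar,
)

__all__ = [
    "DEFAULT_SCORING",
    "ScreenParams",
    "LocalAlignment",
    "ChimeraHit",
    "TrimmedRead",
    "ScreenOutputs",
    "smith_waterman",
    "seed_prefilter",
    "detect_chimera",
    "cigar_prefilter",
    "trim_read",
    "screen_library",
]

#: (match, mismatch, gap open, gap extend); gaps are linear (open == extend)
DEFAULT_SCORING = (2, -3, -4, -4)

#: bait keys whose TE body extends rightward from the match, so the host
#: flank is the read prefix left of the match
_LEFT_FLANK_KEYS = frozenset({"five_prime_fwd", "three_prime_rc"})


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds for chimeric-read detection and trimming.

    Defaults are the tool defaults (15-bp minimum match at 95 % identity);
    screens for older, mutated elements such as HERV-K HML-2 use a 20-bp
    match at 90 % identity with a 20-bp minimum trimmed length.
    """

    min_match_len: int = 15
    min_identity: float = 0.95
    min_trimmed_len: int = 20
    cigar_filter_enabled: bool = False
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING
    prefilter: str = "auto"  # "auto" | "on" | "off"

    def __post_init__(self) -> None:
        if self.min_match_len < 1:
            raise ValueError("min_match_len must be >= 1")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must lie in (0, 1]")
        if self.min_trimmed_len < 1:
            raise ValueError("min_trimmed_len must be >= 1")
        if self.scoring[2] != self.scoring[3]:
            raise NotImplementedError("only linear gap scoring (open == extend) is supported")
        if self.prefilter not in ("auto", "on", "off"):
            raise ValueError("prefilter must be 'auto', 'on' or 'off'")

    @property
    def max_mismatches(self) -> int:
        """Mismatch budget inside a minimum-length match at the identity floor."""
        return math.floor(self.min_match_len * (1 - self.min_identity) + 1e-9)

    @property
    def prefilter_k(self) -> int:
        """Seed length guaranteeing a shared exact k-mer for any in-budget
        substitution-only bait copy (pigeonhole over ``max_mismatches + 1``
        segments)."""
        return self.min_match_len // (self.max_mismatches + 1)

    @property
    def prefilter_active(self) -> bool:
        if self.prefilter == "on":
            return True
        if self.prefilter == "off":
            return False
        return self.prefilter_k >= 4  # shorter seeds match almost every read


@dataclass(frozen=True)
class LocalAlignment:
    """A Smith–Waterman local alignment of a bait within a read.

    Spans are 0-based half-open; ``gaps`` counts gapped positions on either
    sequence.
    """

    score: int
    read_start: int
    read_end: int
    bait_start: int
    bait_end: int
    matches: int
    mismatches: int
    gaps: int


@dataclass(frozen=True)
class ChimeraHit:
    """A read's best passing bait match."""

    read_name: str
    bait_key: str
    read_start: int
    read_end: int
    bait_start: int
    bait_end: int
    matches: int
    mismatches: int
    gaps: int
    score: int
    route: str  # "local" (gapped SW) or "ungapped" (sliding scan)

    @property
    def match_length(self) -> int:
        """Aligned bait positions (matches + mismatches + deleted bait bases)."""
        return self.bait_end - self.bait_start

    @property
    def identity(self) -> float:
        return self.matches / self.match_length

    @property
    def flank_side(self) -> str:
        return "left_of_match" if self.bait_key in _LEFT_FLANK_KEYS else "right_of_match"


@dataclass(frozen=True)
class TrimmedRead:
    """The host-flank portion of a chimeric read after TE removal."""

    read_name: str
    host_flank_seq: str
    host_flank_quals: str
    te_portion_seq: str
    te_portion_quals: str
    flank_side: str
    pair_member: str = "none"
    original_mapping: Optional[tuple[str, int, int, str]] = None  # (ref, pos, mapq, cigar)

    def as_read(self) -> ReadRecord:
        return ReadRecord(self.read_name, self.host_flank_seq, self.host_flank_quals, self.pair_member)

    def te_as_read(self) -> ReadRecord:
        return ReadRecord(self.read_name, self.te_portion_seq, self.te_portion_quals, self.pair_member)


def smith_waterman(
    read_seq: str,
    bait_seq: str,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
) -> Optional[LocalAlignment]:
    """Optimal local alignment of ``bait_seq`` within ``read_seq``.

    Linear gap scoring; deterministic tie-breaking (smallest read start, then
    smallest bait start, then smallest ends). Returns ``None`` when no
    positive-scoring alignment exists.
    """
    if not read_seq or not bait_seq:
        raise ValueError("both sequences must be non-empty")
    if scoring[2] != scoring[3]:
        raise NotImplementedError("only linear gap scoring is supported")
    read = _sw.encode(read_seq)
    bait = _sw.encode(bait_seq)
    H = np.zeros((read.shape[0] + 1, bait.shape[0] + 1), dtype=np.int64)
    score, rs, re_, bs, be, m, x, g = _sw.sw_align(
        read, bait, scoring[0], scoring[1], scoring[2], H
    )
    if score <= 0:
        return None
    return LocalAlignment(int(score), int(rs), int(re_), int(bs), int(be), int(m), int(x), int(g))


def seed_prefilter(
    read_seq: str,
    baitset: BaitSet,
    max_mismatches: int,
    min_match_len: Optional[int] = None,
) -> bool:
    """True iff the read shares an exact k-mer with some bait.

    ``k = floor(min_match_len / (max_mismatches + 1))``, so by pigeonhole the
    filter never rejects a read containing a minimum-length bait copy with at
    most ``max_mismatches`` substitutions. ``min_match_len`` defaults to the
    bait length.
    """
    if min_match_len is None:
        min_match_len = baitset.bait_length
    k = min_match_len // (max_mismatches + 1)
    if k < 1 or len(read_seq) < k:
        return True if k < 1 else False
    kmers = set()
    for bait in baitset.ordered():
        for i in range(len(bait) - k + 1):
            kmers.add(bait[i : i + k])
    seq = read_seq.upper()
    return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))


def cigar_prefilter(record: AlignmentRecord, params: ScreenParams) -> bool:
    """True iff the record is a candidate for novel-integration screening.

    Candidates are reads mapping less than perfectly to the host (match
    fraction below 1.0), unmapped reads, and mapped reads with an undefined
    CIGAR (conservative). With ``cigar_filter_enabled`` these are the only
    reads screened; reference-integration annotation bypasses the filter since
    reads over reference TE copies map perfectly.
    """
    if record.is_unmapped:
        return True
    info = parse_cigar(record.cigar)
    if info.is_undefined:
        return True
    return info.match_fraction < 1.0


def _bait_matrix(baitset: BaitSet) -> np.ndarray:
    return np.stack([_sw.encode(b) for b in baitset.ordered()])


def _hit_from_row(read_name: str, row: np.ndarray) -> Optional[ChimeraHit]:
    if row[0] < 0:
        return None
    return ChimeraHit(
        read_name=read_name,
        bait_key=BAIT_KEYS[int(row[0])],
        read_start=int(row[3]),
        read_end=int(row[4]),
        bait_start=int(row[5]),
        bait_end=int(row[6]),
        matches=int(row[7]),
        mismatches=int(row[8]),
        gaps=int(row[9]),
        score=int(row[2]),
        route="local" if row[1] == 0 else "ungapped",
    )


def detect_chimera(read: ReadRecord, baitset: BaitSet, params: ScreenParams) -> Optional[ChimeraHit]:
    """Best passing bait hit for one read, or ``None``.

    Ties across baits resolve in the fixed bait order (5' forward, 5' reverse
    complement, 3' forward, 3' reverse complement).
    """
    if params.min_match_len > baitset.bait_length:
        raise ValueError(
            f"min_match_len {params.min_match_len} exceeds bait length {baitset.bait_length}"
        )
    codes = _sw.encode(read.sequence)
    baits = _bait_matrix(baitset)
    H = np.zeros((codes.shape[0] + 1, baits.shape[1] + 1), dtype=np.int64)
    out = np.empty(10, dtype=np.int64)
    _sw.screen_read(
        codes,
        baits,
        params.scoring[0],
        params.scoring[1],
        params.scoring[2],
        params.min_match_len,
        params.min_identity,
        H,
        out,
    )
    return _hit_from_row(read.name, out)


def trim_read(read: ReadRecord, hit: ChimeraHit, params: ScreenParams) -> Optional[TrimmedRead]:
    """Remove the TE-matching portion of a chimeric read.

    The retained host flank is the read portion on the host side of the
    junction implied by the bait key: the prefix left of the match for 5'
    forward / 3' reverse-complement baits (TE body extends rightward), the
    suffix right of the match otherwise. The TE portion is the remainder from
    the match boundary through the read end on the TE side, so flank and TE
    portion reassemble the whole read. Returns ``None`` when the flank is
    shorter than ``min_trimmed_len``.
    """
    if hit.read_name != read.name:
        raise ValueError("hit was not produced from this read")
    if hit.flank_side == "left_of_match":
        flank = slice(0, hit.read_start)
        te = slice(hit.read_start, len(read.sequence))
    else:
        flank = slice(hit.read_end, len(read.sequence))
        te = slice(0, hit.read_end)
    host_seq = read.sequence[flank]
    if len(host_seq) < params.min_trimmed_len:
        return None
    return TrimmedRead(
        read_name=read.name,
        host_flank_seq=host_seq,
        host_flank_quals=read.qualities[flank],
        te_portion_seq=read.sequence[te],
        te_portion_quals=read.qualities[te],
        flank_side=hit.flank_side,
        pair_member=read.pair_member,
        original_mapping=None,
    )


# ---------------------------------------------------------------------------
# Library screening


@dataclass
class ScreenOutputs:
    """Paths and tallies of a library screen."""

    trimmed_path: Path
    te_path: Path
    report_path: Path
    mates_path: Optional[Path] = None
    counts: dict[str, int] = field(default_factory=dict)


_REPORT_HEADER = (
    "#read_name\tbait_key\tmatch_length\tpercent_identity\tflank_side\t"
    "orig_reference\torig_position\torig_mapq\torig_cigar\n"
)

_CHUNK_READS = 100_000


def _as_screen_unit(item) -> tuple[ReadRecord, Optional[tuple], Optional[AlignmentRecord]]:
    if isinstance(item, AlignmentRecord):
        mapping = None
        if not item.is_unmapped:
            mapping = (item.reference_name, item.position, item.mapq, item.cigar)
        return item.read, mapping, item
    return item, None, None


def _rolling_codes(mat: np.ndarray, k: int) -> np.ndarray:
    n_windows = mat.shape[1] - k + 1
    acc = np.zeros((mat.shape[0], n_windows), dtype=np.int64)
    for j in range(k):
        acc = acc * 5 + mat[:, j : j + n_windows]
    return acc


def _batch_prefilter(mat: np.ndarray, baitset: BaitSet, params: ScreenParams) -> np.ndarray:
    """Vectorised k-mer membership mask over a padded read-code matrix."""
    k = params.prefilter_k
    if mat.shape[1] < k:
        return np.zeros(mat.shape[0], dtype=bool)
    bait_mat = _bait_matrix(baitset)
    bait_codes = np.unique(_rolling_codes(bait_mat, k))
    codes = _rolling_codes(mat, k)
    return np.isin(codes, bait_codes).any(axis=1)


def _screen_chunk(
    reads: Sequence[ReadRecord],
    baits: np.ndarray,
    baitset: BaitSet,
    params: ScreenParams,
    screenable: np.ndarray,
) -> tuple[list[Optional[ChimeraHit]], int]:
    """Run detection over a chunk; returns per-read hits and the number of
    reads that reached the alignment kernel."""
    n = len(reads)
    hits: list[Optional[ChimeraHit]] = [None] * n
    idx = np.flatnonzero(screenable)
    if idx.size == 0:
        return hits, 0
    maxlen = max(len(reads[i].sequence) for i in idx)
    maxlen = max(maxlen, params.prefilter_k)
    mat = np.full((idx.size, maxlen), 4, dtype=np.uint8)
    lengths = np.empty(idx.size, dtype=np.int64)
    for row, i in enumerate(idx):
        codes = _sw.encode(reads[i].sequence)
        mat[row, : codes.shape[0]] = codes
        lengths[row] = codes.shape[0]
    if params.prefilter_active:
        keep = _batch_prefilter(mat, baitset, params)
    else:
        keep = np.ones(idx.size, dtype=bool)
    krows = np.flatnonzero(keep)
    if krows.size == 0:
        return hits, 0
    out = np.empty((krows.size, 10), dtype=np.int64)
    _sw.screen_batch(
        mat[krows],
        lengths[krows],
        baits,
        params.scoring[0],
        params.scoring[1],
        params.scoring[2],
        params.min_match_len,
        params.min_identity,
        out,
    )
    for row, krow in enumerate(krows):
        i = idx[krow]
        hits[i] = _hit_from_row(reads[i].name, out[row])
    return hits, int(krows.size)


def _chunked(iterator: Iterator, size: int) -> Iterator[list]:
    chunk: list = []
    for item in iterator:
        chunk.append(item)
        if len(chunk) >= size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def screen_library(
    records: Iterable[Union[ReadRecord, AlignmentRecord]],
    baitset: BaitSet,
    params: ScreenParams,
    paired: bool = False,
    out_prefix: Union[str, Path] = "screen",
) -> ScreenOutputs:
    """Screen a read library against a bait set and write the four outputs.

    ``records`` may be raw reads (FASTQ) or alignment records (SAM); paired
    input must be name-collated so mates are adjacent. Outputs are
    ``<prefix>.trimmed.fastq`` (host flanks), ``<prefix>.mates.fastq``
    (paired mode: one mate per trimmed read — the mate's trimmed version when
    the mate is itself chimeric and trimmable, otherwise its original read),
    ``<prefix>.te.fastq`` (removed TE portions) and ``<prefix>.chimera.tsv``.

    With ``cigar_filter_enabled`` only alignment records mapping less than
    perfectly (or unmapped) are searched; their mates are still retrieved.
    """
    if params.min_match_len > baitset.bait_length:
        raise ValueError(
            f"min_match_len {params.min_match_len} exceeds bait length {baitset.bait_length}"
        )
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out = ScreenOutputs(
        trimmed_path=Path(str(prefix) + ".trimmed.fastq"),
        te_path=Path(str(prefix) + ".te.fastq"),
        report_path=Path(str(prefix) + ".chimera.tsv"),
        mates_path=Path(str(prefix) + ".mates.fastq") if paired else None,
    )
    counts = {
        "reads_in": 0,
        "pairs_in": 0,
        "reads_aligned_to_baits": 0,
        "hits": 0,
        "trimmed": 0,
        "discarded_short_flank": 0,
        "discarded_cigar_filter": 0,
        "mates_written": 0,
    }
    baits = _bait_matrix(baitset)

    units = iter(records)
    if paired:
        # group SAM records / reads into adjacent mate pairs
        def _pairs(stream):
            pending = None
            for item in stream:
                aln = item if isinstance(item, AlignmentRecord) else None
                if aln is not None and (aln.is_secondary or aln.is_supplementary):
                    continue
                if pending is None:
                    pending = item
                    continue
                prev_read = pending.read if isinstance(pending, AlignmentRecord) else pending
                cur_read = item.read if isinstance(item, AlignmentRecord) else item
                if prev_read.base_name != cur_read.base_name:
                    raise FormatError(
                        f"orphan read {prev_read.name!r}: next record is {cur_read.name!r}"
                    )
                yield pending, item
                pending = None
            if pending is not None:
                name = (pending.read if isinstance(pending, AlignmentRecord) else pending).name
                raise FormatError(f"orphan read {name!r} at end of input")

        unit_iter = _pairs(units)
        chunk_size = _CHUNK_READS // 2
    else:
        def _singles(stream):
            for item in stream:
                if isinstance(item, AlignmentRecord) and (item.is_secondary or item.is_supplementary):
                    continue
                yield (item,)

        unit_iter = _singles(units)
        chunk_size = _CHUNK_READS

    trimmed_f = open(out.trimmed_path, "w")
    te_f = open(out.te_path, "w")
    report_f = open(out.report_path, "w")
    mates_f = open(out.mates_path, "w") if paired else None
    report_f.write(_REPORT_HEADER)
    try:
        for chunk in _chunked(unit_iter, chunk_size):
            flat_reads: list[ReadRecord] = []
            flat_maps: list[Optional[tuple]] = []
            screenable_flags: list[bool] = []
            unit_spans: list[tuple[int, int]] = []
            for unit in chunk:
                start = len(flat_reads)
                for item in unit:
                    read, mapping, aln = _as_screen_unit(item)
                    flat_reads.append(read)
                    flat_maps.append(mapping)
                    if params.cigar_filter_enabled and aln is not None:
                        ok = cigar_prefilter(aln, params)
                        if not ok:
                            counts["discarded_cigar_filter"] += 1
                        screenable_flags.append(ok)
                    else:
                        screenable_flags.append(True)
                unit_spans.append((start, len(flat_reads)))
            counts["reads_in"] += len(flat_reads)
            if paired:
                counts["pairs_in"] += len(chunk)
            hits, n_aligned = _screen_chunk(
                flat_reads, baits, baitset, params, np.asarray(screenable_flags, dtype=bool)
            )
            counts["reads_aligned_to_baits"] += n_aligned
            for start, end in unit_spans:
                members = list(range(start, end))
                trims: dict[int, Optional[TrimmedRead]] = {}
                for i in members:
                    hit = hits[i]
                    if hit is None:
                        continue
                    counts["hits"] += 1
                    trimmed = trim_read(flat_reads[i], hit, params)
                    if trimmed is None:
                        counts["discarded_short_flank"] += 1
                    elif flat_maps[i] is not None:
                        trimmed = TrimmedRead(
                            **{**trimmed.__dict__, "original_mapping": flat_maps[i]}
                        )
                    trims[i] = trimmed
                for i in members:
                    trimmed = trims.get(i)
                    if trimmed is None:
                        continue
                    counts["trimmed"] += 1
                    rec = trimmed.as_read()
                    trimmed_f.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.qualities}\n")
                    te = trimmed.te_as_read()
                    te_f.write(f"@{te.name}\n{te.sequence}\n+\n{te.qualities}\n")
                    hit = hits[i]
                    om = trimmed.original_mapping
                    om_fields = (
                        (om[0], str(om[1]), str(om[2]), om[3]) if om is not None else (".", ".", ".", ".")
                    )
                    report_f.write(
                        f"{rec.name}\t{hit.bait_key}\t{hit.match_length}\t"
                        f"{100 * hit.identity:.2f}\t{hit.flank_side}\t"
                        + "\t".join(om_fields)
                        + "\n"
                    )
                    if paired and mates_f is not None:
                        other = members[1] if i == members[0] else members[0]
                        other_trim = trims.get(other)
                        mate = (
                            other_trim.as_read() if other_trim is not None else flat_reads[other]
                        )
                        mates_f.write(f"@{mate.name}\n{mate.sequence}\n+\n{mate.qualities}\n")
                        counts["mates_written"] += 1
    finally:
        trimmed_f.close()
        te_f.close()
        report_f.close()
        if mates_f is not None:
            mates_f.close()
    out.counts = counts
    return out
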