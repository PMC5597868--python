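"""Test-scale seed-and-extend read mapper.

Maps trimmed host flanks (single-end) or trimmed-read/mate pairs (guided
detection) back to a host reference so the full pipeline runs without an
external aligner; any aligner's SAM can be substituted downstream. Candidate
loci come from exact k-mer seeds over both read strands; each candidate is
scored by gapless end-to-end comparison under the same match/mismatch scheme
as the bait screen (the simulator's error model is substitution-only, and the
paired mode is end-to-end with no soft clipping anyway). The MAPQ surrogate
is binary: 60 when the best placement is strictly better than the runner-up,
0 otherwise — downstream only uses the uniqueness distinction.

In guided mode a trimmed read that is ambiguous alone is rescued when exactly
one of its candidate loci is compatible (opposite orientation, fragment length
within bounds) with its mate's placement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import _sw
from .formats import AlignmentRecord, ReadRecord, read_fastq, write_sam

__all__ = [
    "MappingParams",
    "ReferenceIndex",
    "index_reference",
    "map_single",
    "map_paired",
    "map_fastq",
]

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_FIRST = 0x40
_FLAG_SECOND = 0x80

MAPQ_UNIQUE = 60


@dataclass(frozen=True)
class MappingParams:
    seed_k: int = 17
    max_hits_reported: int = 10
    pair_min: int = 100
    pair_max: int = 700
    paired_end_to_end: bool = True
    min_identity: float = 0.9
    seed_hit_cap: int = 200  # seeds hitting more loci than this are skipped

    def __post_init__(self) -> None:
        if self.pair_min >= self.pair_max:
            raise ValueError("pair_min must be smaller than pair_max")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")


class ReferenceIndex:
    """Exact k-mer index over the forward strand of each reference contig.

    Reverse-strand hits are found by seeding the read's reverse complement,
    which is equivalent to indexing both strands.
    """

    def __init__(self, sequences: dict[str, str], k: int = 17):
        if not sequences:
            raise ValueError("reference contains no sequences")
        self.k = k
        self.names = list(sequences)
        self.codes: dict[str, np.ndarray] = {}
        self.lengths: dict[str, int] = {}
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in sequences.items():
            codes = _sw.encode(seq)
            if codes.shape[0] < k:
                raise ValueError(f"reference sequence {name!r} shorter than k={k}")
            self.codes[name] = codes
            self.lengths[name] = codes.shape[0]
            kmers = _rolling(codes, k)
            order = np.argsort(kmers, kind="stable").astype(np.int64)
            self._sorted[name] = (kmers[order], order)

    def lookup(self, kmer_code: int, name: str) -> np.ndarray:
        """Sorted 0-based offsets of an exact k-mer on one contig."""
        sorted_kmers, order = self._sorted[name]
        lo = np.searchsorted(sorted_kmers, kmer_code, side="left")
        hi = np.searchsorted(sorted_kmers, kmer_code, side="right")
        return np.sort(order[lo:hi])


def _rolling(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.shape[0] - k + 1
    acc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        acc = acc * 5 + codes[j : j + n]
    return acc


def index_reference(
    reference: Union[str, Path, dict[str, str]], k: int = 17
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from a FASTA path or a name->sequence dict."""
    from .formats import read_fasta

    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    return ReferenceIndex(reference, k=k)


@dataclass(frozen=True)
class _Candidate:
    name: str
    strand: str  # "+" read as given, "-" reverse complement placed
    pos: int  # 0-based leftmost
    score: int
    matches: int

    @property
    def sort_key(self):
        return (-self.score, self.name, self.pos, self.strand)


def _seed_offsets(length: int, k: int) -> list[int]:
    if length < k:
        return []
    offsets = list(range(0, length - k + 1, k))
    if offsets[-1] != length - k:
        offsets.append(length - k)
    return offsets


def _candidates(read_codes: np.ndarray, index: ReferenceIndex, params: MappingParams) -> list[_Candidate]:
    k = index.k
    L = read_codes.shape[0]
    if L < k:
        return []
    rc = (3 - read_codes[::-1]).astype(np.uint8)
    out: list[_Candidate] = []
    seen: set[tuple[str, str, int]] = set()
    for strand, arr in (("+", read_codes), ("-", rc)):
        kmers = _rolling(arr, k)
        for off in _seed_offsets(L, k):
            code = int(kmers[off])
            for name in index.names:
                hits = index.lookup(code, name)
                if hits.size == 0 or hits.size > params.seed_hit_cap:
                    continue
                ref = index.codes[name]
                for p in hits.tolist():
                    start = p - off
                    if start < 0 or start + L > index.lengths[name]:
                        continue  # end-to-end only: no overhanging placements
                    key = (name, strand, start)
                    if key in seen:
                        continue
                    seen.add(key)
                    window = ref[start : start + L]
                    m = int(np.count_nonzero((window == arr) & (window < 4)))
                    x = L - m
                    if m < params.min_identity * L:
                        continue
                    out.append(_Candidate(name, strand, start, 2 * m - 3 * x, m))
    out.sort(key=lambda c: c.sort_key)
    return out


def _record(
    read: ReadRecord,
    cand: Optional[_Candidate],
    mapq: int,
    flag_extra: int = 0,
) -> AlignmentRecord:
    if cand is None:
        return AlignmentRecord(
            read=read,
            reference_name=None,
            position=0,
            cigar="*",
            mapq=0,
            flag=_FLAG_UNMAPPED | flag_extra,
        )
    seq = read.sequence
    qual = read.qualities
    if cand.strand == "-":
        from .baits import reverse_complement

        seq = reverse_complement(seq)
        qual = qual[::-1]
    stored = ReadRecord(read.name, seq, qual, read.pair_member)
    flag = flag_extra | (_FLAG_REVERSE if cand.strand == "-" else 0)
    return AlignmentRecord(
        read=stored,
        reference_name=cand.name,
        position=cand.pos + 1,
        cigar=f"{len(seq)}M",
        mapq=mapq,
        flag=flag,
    )


def map_single(
    read: ReadRecord, index: ReferenceIndex, params: MappingParams = MappingParams()
) -> list[AlignmentRecord]:
    """Map one read; best alignment first, capped at ``max_hits_reported``.

    Reads shorter than the seed length, or without any acceptable placement,
    yield a single unmapped record. The best alignment gets MAPQ 60 iff its
    score strictly exceeds the runner-up's.
    """
    codes = _sw.encode(read.sequence)
    cands = _candidates(codes, index, params)
    if not cands:
        return [_record(read, None, 0)]
    unique = len(cands) == 1 or cands[0].score > cands[1].score
    records = []
    for i, cand in enumerate(cands[: params.max_hits_reported]):
        mapq = (MAPQ_UNIQUE if unique else 0) if i == 0 else 0
        flag_extra = 0 if i == 0 else 0x100  # secondary
        records.append(_record(read, cand, mapq, flag_extra))
    return records


def _pair_orientation_ok(c1: _Candidate, c2: _Candidate) -> bool:
    if c1.name != c2.name or c1.strand == c2.strand:
        return False
    fwd, rev = (c1, c2) if c1.strand == "+" else (c2, c1)
    return fwd.pos <= rev.pos


def _fragment_length(c1: _Candidate, l1: int, c2: _Candidate, l2: int) -> int:
    left = min(c1.pos, c2.pos)
    right = max(c1.pos + l1, c2.pos + l2)
    return right - left


def map_paired(
    trimmed: ReadRecord,
    mate: ReadRecord,
    index: ReferenceIndex,
    params: MappingParams = MappingParams(),
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Jointly place a trimmed read and its mate (guided detection).

    Chooses the placement pair maximising the joint score subject to opposite
    orientation and a fragment length within ``[pair_min, pair_max]``; each
    read's placement is unique (MAPQ 60) iff all top-scoring pairs agree on
    its position. Without any compatible pair, both reads fall back to their
    single-end results (flagged paired, not proper).
    """
    c1 = _candidates(_sw.encode(trimmed.sequence), index, params)
    c2 = _candidates(_sw.encode(mate.sequence), index, params)
    l1, l2 = len(trimmed.sequence), len(mate.sequence)
    combos = []
    for a, b in itertools.product(c1, c2):
        if not _pair_orientation_ok(a, b):
            continue
        frag = _fragment_length(a, l1, b, l2)
        if not (params.pair_min <= frag <= params.pair_max):
            continue
        combos.append((a.score + b.score, a, b, frag))
    flags1 = _FLAG_PAIRED | _FLAG_FIRST
    flags2 = _FLAG_PAIRED | _FLAG_SECOND
    if not combos:
        r1 = _single_in_pair(trimmed, c1, params, flags1)
        r2 = _single_in_pair(mate, c2, params, flags2)
        _cross_annotate(r1, r2)
        return r1, r2
    combos.sort(key=lambda t: (-t[0], t[1].sort_key, t[2].sort_key))
    best_score = combos[0][0]
    top = [c for c in combos if c[0] == best_score]
    _, a, b, frag = combos[0]
    unique1 = len({(c[1].name, c[1].pos, c[1].strand) for c in top}) == 1
    unique2 = len({(c[2].name, c[2].pos, c[2].strand) for c in top}) == 1
    r1 = _record(trimmed, a, MAPQ_UNIQUE if unique1 else 0, flags1 | _FLAG_PROPER)
    r2 = _record(mate, b, MAPQ_UNIQUE if unique2 else 0, flags2 | _FLAG_PROPER)
    _cross_annotate(r1, r2)
    sign1 = 1 if a.pos <= b.pos else -1
    r1.template_length = sign1 * frag
    r2.template_length = -sign1 * frag
    return r1, r2


def _single_in_pair(
    read: ReadRecord, cands: list[_Candidate], params: MappingParams, flags: int
) -> AlignmentRecord:
    if not cands:
        return _record(read, None, 0, flags)
    unique = len(cands) == 1 or cands[0].score > cands[1].score
    return _record(read, cands[0], MAPQ_UNIQUE if unique else 0, flags)


def _cross_annotate(r1: AlignmentRecord, r2: AlignmentRecord) -> None:
    for rec, other in ((r1, r2), (r2, r1)):
        if other.is_unmapped:
            rec.flag |= _FLAG_MATE_UNMAPPED
        else:
            rec.mate_reference_name = other.reference_name
            rec.mate_position = other.position
            if other.is_reverse:
                rec.flag |= _FLAG_MATE_REVERSE


def map_fastq(
    reads: Union[str, Path, Iterable[ReadRecord]],
    index: ReferenceIndex,
    out_sam: Union[str, Path],
    params: MappingParams = MappingParams(),
    mates: Optional[Union[str, Path, Iterable[ReadRecord]]] = None,
) -> int:
    """Map a FASTQ (optionally with a positionally matched mates FASTQ) to SAM.

    With ``mates``, read *i* of ``reads`` pairs with read *i* of ``mates``
    (the layout the screening step emits) and placement is guided; otherwise
    reads map single-end. Returns the number of SAM records written.
    """
    read_iter = read_fastq(reads) if isinstance(reads, (str, Path)) else iter(reads)

    def _records():
        if mates is None:
            for read in read_iter:
                yield from map_single(read, index, params)
        else:
            mate_iter = read_fastq(mates) if isinstance(mates, (str, Path)) else iter(mates)
            for read, mate in zip(read_iter, mate_iter, strict=True):
                r1, r2 = map_paired(read, mate, index, params)
                yield r1
                yield r2

    return write_sam(_records(), out_sam, dict(index.lengths))
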