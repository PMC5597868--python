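"""Synthetic insertion genomes and Illumina-like paired-end reads.

The generator emulates whole-genome resequencing of a host that carries
TE/virus integrations absent from the mapping reference: a uniform-random host
contig stands in for a human chromosome at desk scale, full-length elements or
solo LTRs are inserted with a target-site duplication (TSD), and 2x100-bp
paired reads are drawn at a requested fold coverage with silent substitution
errors (errors are not flagged in the qualities, as in real data).

Read names encode their fragment of origin (``r<i>:<start>:<end>:<strand>``)
so downstream truth checks need no side table; per-fragment origins are also
returned as arrays.

Presets reproduce the simulation designs the detection pipeline is evaluated
on: 20 full-length ~9.7-kb provirus insertions into a 1-Mb host at 50x
(``hiv_like_20``), 10 solo-LTR insertions (``ltr_like_10``), and a
presence/absence design with reads from carrier and non-carrier haplotypes of
a reference that itself contains annotated elements
(``reference_presence_absence``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np

from . import _sw
from .baits import reverse_complement
from .formats import GenomicInterval, ReadRecord, write_bed, write_fasta

__all__ = [
    "SimParams",
    "InsertionTruth",
    "SimReads",
    "Fixture",
    "PRESETS",
    "random_genome",
    "random_element",
    "insert_elements",
    "simulate_reads",
    "make_fixture",
]

HOST_CONTIG = "host1"


def _rng(seed: Union[int, np.random.Generator, np.random.SeedSequence]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimParams:
    """Conditions of a simulated resequencing experiment."""

    host_length: int
    n_insertions: int
    element_sequence: str
    element_name: str = "element"
    tsd_length: int = 5
    coverage: float = 50.0
    read_length: int = 100
    fragment_mean: int = 350
    fragment_sd: int = 50
    error_rate: float = 0.002
    seed: int = 0
    separation: Optional[int] = None

    def __post_init__(self) -> None:
        if self.read_length >= self.fragment_mean:
            raise ValueError("read_length must be smaller than fragment_mean")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")

    @property
    def min_separation(self) -> int:
        """Minimum distance between insertion points.

        At least twice the fragment mean (no fragment spans two insertions)
        and by default 25 kb, so that distinct sites stay farther apart than
        the downstream clustering range — the designs being emulated scatter
        a handful of insertions over a whole chromosome, where two sites
        within clustering range essentially never occur. On a desk-scale host
        that sparsity must be imposed rather than left to chance.
        """
        if self.separation is not None:
            return max(self.separation, 2 * self.fragment_mean)
        return max(2 * self.fragment_mean, 25_000)

    @property
    def end_margin(self) -> int:
        return self.fragment_mean


@dataclass(frozen=True)
class InsertionTruth:
    """A simulated insertion site in pre-insertion host coordinates."""

    position: int
    element_name: str
    orientation: str  # "forward" | "reverse"
    tsd_length: int


def random_genome(length: int, seed: Union[int, np.random.Generator]) -> str:
    """Uniform i.i.d. A/C/G/T contig of at least 10 kb; deterministic per seed."""
    if length < 10_000:
        raise ValueError(f"host length {length} < 10,000")
    rng = _rng(seed)
    return _sw.decode(rng.integers(0, 4, size=length).astype(np.uint8))


def random_element(length: int, seed: Union[int, np.random.Generator]) -> str:
    """Uniform-random element sequence (no minimum length)."""
    if length < 1:
        raise ValueError("element length must be >= 1")
    rng = _rng(seed)
    return _sw.decode(rng.integers(0, 4, size=length).astype(np.uint8))


def insert_elements(
    host: str,
    element: str,
    n: int,
    tsd_length: int,
    seed: Union[int, np.random.Generator],
    element_name: str = "element",
    min_separation: int = 700,
    end_margin: int = 350,
) -> tuple[str, list[InsertionTruth]]:
    """Insert ``n`` element copies into ``host`` at random well-separated sites.

    At each site the ``tsd_length`` host bases immediately left of the
    insertion point are duplicated after the element, mimicking the
    target-site duplication of integration. Orientation is random per site.
    The returned genome has length ``len(host) + n * (len(element) +
    tsd_length)``; truth positions are strictly increasing pre-insertion host
    coordinates.
    """
    if n == 0:
        return host, []
    rng = _rng(seed)
    usable = len(host) - 2 * end_margin - (n - 1) * min_separation
    if usable < n:
        raise ValueError(
            f"cannot place {n} insertions {min_separation} bp apart in a "
            f"{len(host)}-bp host; use a larger host or fewer insertions"
        )
    offsets = np.sort(rng.choice(usable, size=n, replace=False))
    positions = end_margin + offsets + np.arange(n) * min_separation
    orientations = np.where(rng.random(n) < 0.5, "forward", "reverse")
    pieces: list[str] = []
    truths: list[InsertionTruth] = []
    prev = 0
    for p, orient in zip(positions.tolist(), orientations.tolist()):
        inserted = element if orient == "forward" else reverse_complement(element)
        pieces.append(host[prev:p])
        pieces.append(inserted)
        if tsd_length:
            pieces.append(host[p - tsd_length : p])
        prev = p
        truths.append(InsertionTruth(p, element_name, orient, tsd_length))
    pieces.append(host[prev:])
    return "".join(pieces), truths


def element_intervals_in_genome(
    truths: Sequence[InsertionTruth], element_length: int, chrom: str = HOST_CONTIG
) -> list[GenomicInterval]:
    """Element spans in post-insertion genome coordinates, one per truth site."""
    intervals = []
    added = 0
    for t in truths:
        start = t.position + added
        intervals.append(GenomicInterval(chrom, start, start + element_length, t.element_name))
        added += element_length + t.tsd_length
    return intervals


@dataclass
class SimReads:
    """Outcome of a read simulation."""

    n_pairs: int
    total_bases: int
    fragment_starts: np.ndarray
    fragment_ends: np.ndarray
    strands: np.ndarray  # "+" read1 is the forward left end, "-" flipped
    records: Optional[list[ReadRecord]] = None


def simulate_reads(
    genome: str,
    params: SimParams,
    out_fastq: Optional[Union[str, Path, IO[str]]] = None,
) -> SimReads:
    """Draw name-collated Illumina-like read pairs from ``genome``.

    The number of pairs is ``ceil(coverage * len(genome) / (2 *
    read_length))``; fragment lengths are Normal(mean, sd) truncated to at
    least one read length; substitution errors hit each base independently at
    ``error_rate`` and are silent (constant high qualities). Read 2 is the
    reverse complement of the fragment's other end; with probability 1/2 the
    fragment is sequenced from the opposite strand and the mates swap roles.

    When ``out_fastq`` is given the interleaved FASTQ is written there;
    otherwise the records are returned in memory.
    """
    G = len(genome)
    if G <= params.fragment_mean + 4 * params.fragment_sd:
        raise ValueError("genome too short for the fragment-length distribution")
    rl = params.read_length
    rng = np.random.default_rng(params.seed)
    n = math.ceil(params.coverage * G / (2 * rl))

    frags = np.rint(rng.normal(params.fragment_mean, params.fragment_sd, size=n)).astype(np.int64)
    while True:  # truncate (resample) below one read length; cap at the genome
        bad = (frags < rl) | (frags > G)
        if not bad.any():
            break
        frags[bad] = np.rint(
            rng.normal(params.fragment_mean, params.fragment_sd, size=int(bad.sum()))
        ).astype(np.int64)
    starts = np.floor(rng.random(n) * (G - frags + 1)).astype(np.int64)
    ends = starts + frags
    flip = rng.random(n) < 0.5

    codes = _sw.encode(genome)
    offs = np.arange(rl)
    left = codes[starts[:, None] + offs]
    right_rc = 3 - codes[(ends - 1)[:, None] - offs]
    read1 = np.where(flip[:, None], right_rc, left).astype(np.uint8)
    read2 = np.where(flip[:, None], left, right_rc).astype(np.uint8)
    del left, right_rc

    if params.error_rate > 0:
        for mat in (read1, read2):
            mask = rng.random(mat.shape) < params.error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()))
            mat[mask] = (mat[mask] + shift) % 4

    strands = np.where(flip, "-", "+")
    qual = "I" * rl
    result = SimReads(
        n_pairs=n,
        total_bases=2 * rl * n,
        fragment_starts=starts,
        fragment_ends=ends,
        strands=strands,
    )

    def _emit():
        for i in range(n):
            name = f"r{i}:{starts[i]}:{ends[i]}:{strands[i]}"
            yield name, _sw.decode(read1[i]), _sw.decode(read2[i])

    if out_fastq is None:
        records: list[ReadRecord] = []
        for name, s1, s2 in _emit():
            records.append(ReadRecord(f"{name}/1", s1, qual, "first"))
            records.append(ReadRecord(f"{name}/2", s2, qual, "second"))
        result.records = records
        return result

    handle = open(out_fastq, "w") if isinstance(out_fastq, (str, Path)) else out_fastq
    try:
        buf: list[str] = []
        for name, s1, s2 in _emit():
            buf.append(f"@{name}/1\n{s1}\n+\n{qual}\n@{name}/2\n{s2}\n+\n{qual}\n")
            if len(buf) >= 10_000:
                handle.write("".join(buf))
                buf.clear()
        handle.write("".join(buf))
    finally:
        if isinstance(out_fastq, (str, Path)):
            handle.close()
    return result


# ---------------------------------------------------------------------------
# Presets

PRESETS: dict[str, dict] = {
    # 20 full-length ~9.7-kb provirus insertions, 2x100 bp at 50x
    "hiv_like_20": dict(
        host_length=1_000_000,
        n_insertions=20,
        element_length=9_719,
        element_name="provirus",
        coverage=50.0,
        read_length=100,
    ),
    # 10 solo-LTR insertions, 2x101 bp at 50x
    "ltr_like_10": dict(
        host_length=600_000,
        n_insertions=10,
        element_length=968,
        element_name="solo_ltr",
        coverage=50.0,
        read_length=101,
    ),
    # reference carries annotated elements; reads from carrier and
    # non-carrier haplotypes
    "reference_presence_absence": dict(
        host_length=300_000,
        n_insertions=4,
        element_length=968,
        element_name="ref_element",
        coverage=30.0,
        read_length=100,
    ),
}


@dataclass
class Fixture:
    """File bundle produced by :func:`make_fixture`."""

    preset: str
    params: SimParams
    out_dir: Path
    element_sequence: str
    truths: list[InsertionTruth]
    host_fasta: Path
    element_fasta: Path
    truth_bed: Path
    reads_fastq: Optional[Path] = None
    genome_fasta: Optional[Path] = None
    annotation_bed: Optional[Path] = None
    carrier_fastq: Optional[Path] = None
    noncarrier_fastq: Optional[Path] = None
    n_pairs: dict[str, int] = field(default_factory=dict)


def make_fixture(
    preset_name: str,
    out_dir: Union[str, Path],
    seed: int = 1,
    **overrides,
) -> Fixture:
    """Generate a complete simulation bundle for one preset.

    ``overrides`` may adjust any preset knob (``host_length``, ``coverage``,
    ``element_length``, ``n_insertions``, ``read_length``, ``error_rate``,
    ``tsd_length``); sizes below the preset defaults are convenient for quick
    tests. All randomness derives from ``seed``.
    """
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}")
    conf = {**PRESETS[preset_name], **overrides}
    element_length = conf.pop("element_length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    s_host, s_elem, s_ins, s_reads, s_reads2 = [
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)
    ]

    host = random_genome(conf["host_length"], s_host)
    element = random_element(element_length, s_elem)
    params = SimParams(element_sequence=element, seed=s_reads, **conf)

    genome, truths = insert_elements(
        host,
        element,
        params.n_insertions,
        params.tsd_length,
        s_ins,
        element_name=params.element_name,
        min_separation=params.min_separation,
        end_margin=params.end_margin,
    )

    fx = Fixture(
        preset=preset_name,
        params=params,
        out_dir=out_dir,
        element_sequence=element,
        truths=truths,
        host_fasta=out_dir / "host.fasta",
        element_fasta=out_dir / "element.fasta",
        truth_bed=out_dir / "truth.bed",
    )
    write_fasta({HOST_CONTIG: host}, fx.host_fasta)
    write_fasta({params.element_name: element}, fx.element_fasta)
    truth_intervals = [
        GenomicInterval(HOST_CONTIG, t.position, t.position + 1, f"{t.element_name}:{t.orientation}")
        for t in truths
    ]
    write_bed(truth_intervals, fx.truth_bed)

    if preset_name == "reference_presence_absence":
        # the inserted genome IS the mapping reference; carrier reads come
        # from it, non-carrier reads from the element-free haplotype
        fx.genome_fasta = out_dir / "reference.fasta"
        write_fasta({HOST_CONTIG: genome}, fx.genome_fasta)
        fx.annotation_bed = out_dir / "annotation.bed"
        write_bed(element_intervals_in_genome(truths, len(element)), fx.annotation_bed)
        fx.carrier_fastq = out_dir / "carrier.fastq"
        fx.noncarrier_fastq = out_dir / "noncarrier.fastq"
        res_c = simulate_reads(genome, params, fx.carrier_fastq)
        res_n = simulate_reads(host, replace(params, seed=s_reads2), fx.noncarrier_fastq)
        fx.n_pairs = {"carrier": res_c.n_pairs, "noncarrier": res_n.n_pairs}
    else:
        fx.genome_fasta = out_dir / "inserted_genome.fasta"
        write_fasta({HOST_CONTIG: genome}, fx.genome_fasta)
        fx.reads_fastq = out_dir / "reads.fastq"
        res = simulate_reads(genome, params, fx.reads_fastq)
        fx.n_pairs = {"reads": res.n_pairs}
    return fx
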