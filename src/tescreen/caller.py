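"""Integration-site calling from remapped trimmed reads.

Mapped host flanks are chained into single-linkage clusters (consecutive
reads whose start positions lie within ``cluster_gap``). Known annotated
integrations are marked present on a single read's evidence within
``known_window`` of either annotated edge, and absent at zero support.
Novel candidates require ``min_novel_reads`` clustered reads and must not lie
within ``proximity_exclusion`` of any annotated TE/SVA interval (SVA-like
elements share LTR-derived sequence with the baits and would cross-react);
excluded clusters are reported with their reason rather than dropped.

Only uniquely placed reads support calls: primary mapped records with a
positive MAPQ, and in guided SAM only the trimmed read of each pair (the
first-in-pair record) — the mate's role is to resolve the trimmed read's
placement, not to add support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .formats import (
    AlignmentRecord,
    GenomicInterval,
    read_bed,
    read_sam,
    write_bed,
)
from .simulate import InsertionTruth

__all__ = [
    "CallerParams",
    "Cluster",
    "IntegrationCall",
    "EvalResult",
    "cluster_reads",
    "annotate_known",
    "call_novel",
    "evaluate_against_truth",
    "detect_integrations",
]


@dataclass(frozen=True)
class CallerParams:
    cluster_gap: int = 10_000
    min_novel_reads: int = 5
    known_window: int = 100
    proximity_exclusion: int = 1_000
    min_mapq: int = 1

    def __post_init__(self) -> None:
        for name in ("cluster_gap", "min_novel_reads", "known_window", "proximity_exclusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Cluster:
    """A chained group of mapped trimmed reads on one chromosome."""

    chrom: str
    start: int  # 0-based inclusive, min read start
    end: int  # 0-based exclusive, max read end
    members: list[tuple[str, int, int]]  # (read name, start0, end0)

    @property
    def n_reads(self) -> int:
        return len(self.members)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, score=self.n_reads)


@dataclass
class IntegrationCall:
    interval: GenomicInterval
    supporting_reads: int
    status: str  # known_present | known_absent | novel_candidate
    in_repeat: bool = False
    excluded_reason: Optional[str] = None  # near_known_element | sva_overlap

    def __post_init__(self) -> None:
        if self.status == "known_present" and self.supporting_reads < 1:
            raise ValueError("known_present requires at least one supporting read")
        if self.status == "known_absent" and self.supporting_reads != 0:
            raise ValueError("known_absent requires zero supporting reads")


def usable_alignments(
    records: Iterable[AlignmentRecord], params: CallerParams
) -> list[AlignmentRecord]:
    """Alignments eligible to support calls.

    Primary mapped records at or above ``min_mapq``; from paired (guided)
    records only the first in pair, which carries the trimmed read.
    """
    out = []
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapq < params.min_mapq:
            continue
        if rec.is_paired and not rec.is_first_in_pair:
            continue
        out.append(rec)
    return out


def cluster_reads(
    alignments: Sequence[AlignmentRecord], params: CallerParams
) -> list[Cluster]:
    """Single-linkage chaining per chromosome.

    Consecutive position-sorted reads whose starts are within ``cluster_gap``
    join one cluster; the cluster interval spans the minimum read start to the
    maximum read end. Every input alignment belongs to exactly one cluster.
    """
    by_pos = sorted(alignments, key=lambda r: (r.reference_name, r.position))
    clusters: list[Cluster] = []
    current: Optional[Cluster] = None
    prev_start = 0
    for rec in by_pos:
        start0 = rec.position - 1
        end0 = rec.reference_end
        if (
            current is not None
            and rec.reference_name == current.chrom
            and start0 - prev_start <= params.cluster_gap
        ):
            current.members.append((rec.read.name, start0, end0))
            current.end = max(current.end, end0)
        else:
            current = Cluster(rec.reference_name, start0, end0, [(rec.read.name, start0, end0)])
            clusters.append(current)
        prev_start = start0
    return clusters


def _gap_to_point(start: int, end: int, point: int) -> int:
    if point < start:
        return start - point
    if point > end:
        return point - end
    return 0


def annotate_known(
    clusters: Sequence[Cluster],
    known_integrations: Sequence[GenomicInterval],
    params: CallerParams,
) -> list[IntegrationCall]:
    """Mark each known locus present or absent with its supporting-read count.

    A locus is present iff at least one trimmed-read alignment lies within
    ``known_window`` of either annotated edge (single-read evidence suffices
    for catalogued integrations). With an empty annotation a warning is
    emitted and no calls are returned.
    """
    if not known_integrations:
        warnings.warn("empty known-integration annotation: every cluster is a novel-candidate input")
        return []
    members = [
        (chrom, s, e)
        for cl in clusters
        for (_, s, e) in cl.members
        for chrom in (cl.chrom,)
    ]
    calls = []
    for locus in known_integrations:
        count = 0
        for chrom, s, e in members:
            if chrom != locus.chrom:
                continue
            near = min(
                _gap_to_point(s, e, locus.start),
                _gap_to_point(s, e, locus.end),
            )
            if near <= params.known_window:
                count += 1
        status = "known_present" if count >= 1 else "known_absent"
        calls.append(
            IntegrationCall(
                interval=GenomicInterval(locus.chrom, locus.start, locus.end, locus.name, count),
                supporting_reads=count,
                status=status,
            )
        )
    return calls


def _min_gap(interval: GenomicInterval, annotation: Sequence[GenomicInterval]) -> Optional[int]:
    gaps = [g for iv in annotation if (g := interval.distance_to(iv)) is not None]
    return min(gaps) if gaps else None


def call_novel(
    clusters: Sequence[Cluster],
    known_integrations: Sequence[GenomicInterval],
    sva_annotation: Sequence[GenomicInterval],
    repeat_annotation: Sequence[GenomicInterval],
    params: CallerParams,
) -> tuple[list[IntegrationCall], list[IntegrationCall]]:
    """Novel-integration candidates plus the exclusion ledger.

    A cluster becomes a candidate with at least ``min_novel_reads`` members;
    clusters overlapping an SVA interval are excluded (``sva_overlap``), and
    clusters within ``proximity_exclusion`` (inclusive) of any known or SVA
    interval are excluded (``near_known_element``). ``in_repeat`` flags
    overlap with the repeat annotation. Annotations may be empty (non-
    endogenised elements need none).
    """
    novel: list[IntegrationCall] = []
    excluded: list[IntegrationCall] = []
    for i, cl in enumerate(clusters):
        if cl.n_reads < params.min_novel_reads:
            continue
        iv = GenomicInterval(cl.chrom, cl.start, cl.end, f"novel_{len(novel) + len(excluded) + 1}", cl.n_reads)
        sva_gap = _min_gap(iv, sva_annotation)
        known_gap = _min_gap(iv, known_integrations)
        reason = None
        if sva_gap == 0:
            reason = "sva_overlap"
        else:
            gaps = [g for g in (sva_gap, known_gap) if g is not None]
            if gaps and min(gaps) <= params.proximity_exclusion:
                reason = "near_known_element"
        in_repeat = _min_gap(iv, repeat_annotation) == 0
        call = IntegrationCall(
            interval=iv,
            supporting_reads=cl.n_reads,
            status="novel_candidate",
            in_repeat=in_repeat,
            excluded_reason=reason,
        )
        if reason is None:
            novel.append(call)
        else:
            excluded.append(call)
    return novel, excluded


@dataclass
class EvalResult:
    recovered_count: int
    per_site_support: list[int]  # aligned with the truth list; 0 when missed
    false_positive_count: int
    matched_call_index: list[Optional[int]]


def evaluate_against_truth(
    calls: Sequence[IntegrationCall],
    truths: Sequence[Union[InsertionTruth, tuple[str, int]]],
    tolerance: int = 100,
    chrom: str = "host1",
) -> EvalResult:
    """Score calls against simulated insertion sites.

    A truth site is recovered iff some call's interval edge lies within
    ``tolerance`` of it; matching is nearest-first greedy with each call
    matching at most one site. Unmatched calls count as false positives.
    ``truths`` may be :class:`InsertionTruth` objects (on ``chrom``) or
    ``(chrom, position)`` pairs.
    """
    sites = [
        (t.position, chrom) if isinstance(t, InsertionTruth) else (t[1], t[0])
        for t in truths
    ]
    pairs = []
    for ti, (pos, tchrom) in enumerate(sites):
        for ci, call in enumerate(calls):
            if call.interval.chrom != tchrom:
                continue
            d = min(abs(call.interval.start - pos), abs(call.interval.end - pos))
            if d <= tolerance:
                pairs.append((d, ti, ci))
    pairs.sort()
    matched_truth: dict[int, int] = {}
    used_calls: set[int] = set()
    for d, ti, ci in pairs:
        if ti in matched_truth or ci in used_calls:
            continue
        matched_truth[ti] = ci
        used_calls.add(ci)
    support = [
        calls[matched_truth[ti]].supporting_reads if ti in matched_truth else 0
        for ti in range(len(sites))
    ]
    return EvalResult(
        recovered_count=len(matched_truth),
        per_site_support=support,
        false_positive_count=len(calls) - len(used_calls),
        matched_call_index=[matched_truth.get(ti) for ti in range(len(sites))],
    )


@dataclass
class DetectionResult:
    clusters: list[Cluster]
    novel: list[IntegrationCall]
    known: list[IntegrationCall]
    excluded: list[IntegrationCall]
    novel_bed: Path
    known_bed: Path
    exclusions_tsv: Path


def detect_integrations(
    sam: Union[str, Path, Iterable[AlignmentRecord]],
    out_prefix: Union[str, Path],
    params: CallerParams = CallerParams(),
    known_bed: Optional[Union[str, Path]] = None,
    sva_bed: Optional[Union[str, Path]] = None,
    repeats_bed: Optional[Union[str, Path]] = None,
) -> DetectionResult:
    """Run clustering, known-locus annotation and novel calling on a SAM.

    Writes ``<prefix>.novel.bed`` and ``<prefix>.known.bed`` (present and
    absent loci distinguished in the name column, supporting counts in the
    score column, repeat overlap in the flag column) plus
    ``<prefix>.exclusions.tsv``.
    """
    records = read_sam(sam) if isinstance(sam, (str, Path)) else sam
    alignments = usable_alignments(records, params)
    clusters = cluster_reads(alignments, params)
    known_iv = read_bed(known_bed) if known_bed else []
    sva_iv = read_bed(sva_bed) if sva_bed else []
    repeat_iv = read_bed(repeats_bed) if repeats_bed else []
    if known_iv:
        known = annotate_known(clusters, known_iv, params)
    else:
        known = []
    novel, excluded = call_novel(clusters, known_iv, sva_iv, repeat_iv, params)

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    novel_bed = Path(str(prefix) + ".novel.bed")
    known_bed_out = Path(str(prefix) + ".known.bed")
    exclusions = Path(str(prefix) + ".exclusions.tsv")
    write_bed(
        [c.interval for c in novel],
        novel_bed,
        flags=["repeat" if c.in_repeat else "." for c in novel],
    )
    write_bed(
        [
            GenomicInterval(
                c.interval.chrom,
                c.interval.start,
                c.interval.end,
                f"{c.interval.name}|{'present' if c.status == 'known_present' else 'absent'}",
                c.supporting_reads,
            )
            for c in known
        ],
        known_bed_out,
        flags=["." for _ in known],
    )
    with open(exclusions, "w") as handle:
        handle.write("#chrom\tstart\tend\tsupporting_reads\treason\n")
        for c in excluded:
            handle.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.supporting_reads}\t{c.excluded_reason}\n"
            )
    return DetectionResult(clusters, novel, known, excluded, novel_bed, known_bed_out, exclusions)
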