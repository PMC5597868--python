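"""Clustering, presence/absence annotation, novel calling and truth scoring."""

from __future__ import annotations

import numpy as np
import pytest

from tescreen.caller import (
    CallerParams,
    IntegrationCall,
    annotate_known,
    call_novel,
    cluster_reads,
    detect_integrations,
    evaluate_against_truth,
    usable_alignments,
)
from tescreen.formats import AlignmentRecord, GenomicInterval, ReadRecord, read_bed


def _aln(name, chrom, pos, length=50, mapq=60, flag=0):
    return AlignmentRecord(
        read=ReadRecord(name, "A" * length, "I" * length),
        reference_name=chrom,
        position=pos,
        cigar=f"{length}M",
        mapq=mapq,
        flag=flag,
    )


def _cluster_at(chrom, positions, params=CallerParams(), length=50):
    return cluster_reads(
        [_aln(f"r{i}", chrom, p, length) for i, p in enumerate(positions)], params
    )


PARAMS = CallerParams()


class TestClusterReads:
    def test_five_reads_within_range_form_one_cluster(self):
        clusters = _cluster_at("chr1", [100, 200, 300, 400, 500])
        assert len(clusters) == 1
        assert clusters[0].n_reads == 5
        assert (clusters[0].start, clusters[0].end) == (99, 549)

    def test_gap_beyond_threshold_splits_clusters(self):
        clusters = _cluster_at("chr1", [1_000, 1_100, 1_200, 50_000, 50_100, 50_200])
        assert [c.n_reads for c in clusters] == [3, 3]

    def test_boundary_gap_chains_inclusive(self):
        assert len(_cluster_at("chr1", [1_000, 11_000])) == 1  # gap == 10 kb joins
        assert len(_cluster_at("chr1", [1_000, 11_001])) == 2

    def test_chromosomes_never_co_cluster(self):
        clusters = cluster_reads(
            [_aln("a", "chr1", 100), _aln("b", "chr2", 100)], PARAMS
        )
        assert len(clusters) == 2

    def test_partition_conserves_reads(self):
        rng = np.random.default_rng(8)
        alns = [
            _aln(f"r{i}", f"chr{int(rng.integers(1, 4))}", int(rng.integers(1, 500_000)))
            for i in range(300)
        ]
        clusters = cluster_reads(alns, PARAMS)
        assert sum(c.n_reads for c in clusters) == len(alns)
        names = sorted(m[0] for c in clusters for m in c.members)
        assert names == sorted(a.read.name for a in alns)


class TestAnnotateKnown:
    KNOWN = [GenomicInterval("chr1", 10_000, 10_968, "ltr_locus")]

    def test_single_read_near_edge_marks_presence(self):
        clusters = _cluster_at("chr1", [9_931])  # read end 9980, 20 bp from edge
        calls = annotate_known(clusters, self.KNOWN, PARAMS)
        assert calls[0].status == "known_present"
        assert calls[0].supporting_reads == 1

    def test_no_reads_marks_absence(self):
        calls = annotate_known([], self.KNOWN, PARAMS)
        assert calls[0].status == "known_absent"
        assert calls[0].supporting_reads == 0

    def test_read_beyond_window_does_not_support(self):
        clusters = _cluster_at("chr1", [9_800])  # read spans 9799-9849, gap 151
        calls = annotate_known(clusters, self.KNOWN, PARAMS)
        assert calls[0].status == "known_absent"

    def test_window_boundary_inclusive(self):
        # read end at 9900 exactly 100 bp from the 10000 edge
        clusters = _cluster_at("chr1", [9_851])
        assert annotate_known(clusters, self.KNOWN, PARAMS)[0].status == "known_present"

    def test_empty_annotation_warns(self):
        with pytest.warns(UserWarning, match="empty known-integration"):
            assert annotate_known(_cluster_at("chr1", [5]), [], PARAMS) == []


class TestCallNovel:
    def test_five_reads_make_a_candidate_four_do_not(self):
        five = _cluster_at("chr1", [10_000 + 100 * i for i in range(5)])
        four = _cluster_at("chr1", [10_000 + 100 * i for i in range(4)])
        novel5, _ = call_novel(five, [], [], [], PARAMS)
        novel4, _ = call_novel(four, [], [], [], PARAMS)
        assert len(novel5) == 1 and novel5[0].supporting_reads == 5
        assert novel4 == []

    def test_proximity_exclusion_boundary(self):
        clusters = _cluster_at("chr1", [10_000 + 50 * i for i in range(5)])
        end = clusters[0].end  # 10249
        at_1000 = [GenomicInterval("chr1", end + 1_000, end + 1_500, "sva")]
        at_1001 = [GenomicInterval("chr1", end + 1_001, end + 1_500, "sva")]
        novel, excluded = call_novel(clusters, [], at_1000, [], PARAMS)
        assert novel == [] and excluded[0].excluded_reason == "near_known_element"
        novel, excluded = call_novel(clusters, [], at_1001, [], PARAMS)
        assert len(novel) == 1 and excluded == []

    def test_sva_overlap_reason(self):
        clusters = _cluster_at("chr1", [10_000 + 50 * i for i in range(5)])
        sva = [GenomicInterval("chr1", 10_100, 10_150, "sva")]
        novel, excluded = call_novel(clusters, [], sva, [], PARAMS)
        assert novel == [] and excluded[0].excluded_reason == "sva_overlap"

    def test_near_known_integration_excluded(self):
        clusters = _cluster_at("chr1", [10_000 + 50 * i for i in range(5)])
        known = [GenomicInterval("chr1", clusters[0].end + 800, clusters[0].end + 1_000, "hk2")]
        novel, excluded = call_novel(clusters, known, [], [], PARAMS)
        assert novel == [] and excluded[0].excluded_reason == "near_known_element"

    def test_repeat_overlap_flagged_not_excluded(self):
        clusters = _cluster_at("chr1", [10_000 + 50 * i for i in range(5)])
        repeats = [GenomicInterval("chr1", 10_100, 10_150, "alu")]
        novel, excluded = call_novel(clusters, [], [], repeats, PARAMS)
        assert len(novel) == 1 and novel[0].in_repeat and excluded == []

    def test_thresholds_are_monotone(self):
        rng = np.random.default_rng(9)
        positions = sorted(int(p) for p in rng.integers(1, 2_000_000, size=400))
        clusters = _cluster_at("chr1", positions)
        sva = [GenomicInterval("chr1", s, s + 500) for s in range(50_000, 2_000_000, 200_000)]
        counts_by_min = []
        for min_reads in (2, 3, 5, 8):
            p = CallerParams(min_novel_reads=min_reads)
            counts_by_min.append(len(call_novel(clusters, [], sva, [], p)[0]))
        assert counts_by_min == sorted(counts_by_min, reverse=True)
        counts_by_prox = []
        for prox in (200, 1_000, 5_000, 20_000):
            p = CallerParams(proximity_exclusion=prox)
            counts_by_prox.append(len(call_novel(clusters, [], sva, [], p)[0]))
        assert counts_by_prox == sorted(counts_by_prox, reverse=True)


def _call(chrom, start, end, n=10):
    return IntegrationCall(
        interval=GenomicInterval(chrom, start, end, score=n),
        supporting_reads=n,
        status="novel_candidate",
    )


class TestEvaluateAgainstTruth:
    def test_calls_at_all_sites_recover_everything(self):
        truth = [("chr1", 10_000), ("chr1", 50_000), ("chr1", 90_000)]
        calls = [_call("chr1", p - 40, p + 40, n=7) for _, p in truth]
        res = evaluate_against_truth(calls, truth, tolerance=100)
        assert res.recovered_count == 3
        assert res.false_positive_count == 0
        assert res.per_site_support == [7, 7, 7]

    def test_empty_call_set_recovers_nothing(self):
        res = evaluate_against_truth([], [("chr1", 10_000)], tolerance=100)
        assert res.recovered_count == 0 and res.false_positive_count == 0

    def test_call_beyond_tolerance_is_a_false_positive(self):
        res = evaluate_against_truth(
            [_call("chr1", 10_250, 10_400)], [("chr1", 10_000)], tolerance=100
        )
        assert res.recovered_count == 0 and res.false_positive_count == 1

    def test_each_call_matches_at_most_one_site(self):
        truth = [("chr1", 10_000), ("chr1", 10_150)]
        res = evaluate_against_truth(
            [_call("chr1", 9_990, 10_060)], truth, tolerance=100
        )
        assert res.recovered_count == 1  # one call cannot recover both

    def test_nearest_first_greedy_assignment(self):
        truth = [("chr1", 10_000)]
        near = _call("chr1", 9_995, 10_040, n=5)
        far = _call("chr1", 10_080, 10_200, n=9)
        res = evaluate_against_truth([far, near], truth, tolerance=100)
        assert res.per_site_support == [5]  # the nearer call is matched
        assert res.false_positive_count == 1


class TestDetectIntegrations:
    def test_usable_alignments_filtering(self):
        records = [
            _aln("ok", "chr1", 100),
            _aln("low_mapq", "chr1", 200, mapq=0),
            _aln("secondary", "chr1", 300, flag=0x100),
            _aln("mate", "chr1", 400, flag=0x1 | 0x80),  # second in pair
            _aln("trimmed", "chr1", 500, flag=0x1 | 0x40),  # first in pair
        ]
        names = [r.read.name for r in usable_alignments(records, PARAMS)]
        assert names == ["ok", "trimmed"]

    def test_bed_outputs(self, tmp_path):
        alns = [_aln(f"r{i}", "chr1", 10_000 + 60 * i) for i in range(6)]
        alns += [_aln("near_known", "chr1", 500_000)]
        known = [GenomicInterval("chr1", 499_900, 500_800, "ltr_locus")]
        from tescreen.formats import write_bed

        known_bed = tmp_path / "known.bed"
        write_bed(known, known_bed)
        from tescreen.formats import write_sam

        sam = tmp_path / "in.sam"
        write_sam(alns, sam, {"chr1": 1_000_000})
        result = detect_integrations(
            sam, out_prefix=tmp_path / "out", known_bed=known_bed
        )
        novel = read_bed(result.novel_bed)
        assert len(novel) == 1 and novel[0].score == 6
        known_calls = read_bed(result.known_bed)
        assert known_calls[0].name == "ltr_locus|present"
        assert known_calls[0].score == 1
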