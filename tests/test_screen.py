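"""Chimeric-read detection, trimming, prefiltering and library screening."""

from __future__ import annotations

import io
import itertools

import numpy as np
import pytest

from tescreen import _sw
from tescreen.baits import make_baits, reverse_complement
from tescreen.formats import AlignmentRecord, ReadRecord, read_fastq
from tescreen.screen import (
    ScreenParams,
    cigar_prefilter,
    detect_chimera,
    screen_library,
    seed_prefilter,
    smith_waterman,
    trim_read,
)
from tescreen.simulate import element_intervals_in_genome, random_element

from _oracle import sw_score_bruteforce


def _mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _read(seq: str, name: str = "r") -> ReadRecord:
    return ReadRecord(name, seq, "I" * len(seq))


class TestSmithWaterman:
    def test_exact_embedding_scores_full_match(self, ltr_baits):
        bait = ltr_baits.baits["five_prime_fwd"]
        read = random_element(40, 7) + bait + random_element(40, 8)
        aln = smith_waterman(read, bait)
        assert aln.matches == 20 and aln.mismatches == 0 and aln.gaps == 0
        assert aln.read_start == 40 and aln.read_end == 60
        assert aln.score == 40

    def test_two_substitutions_give_ninety_percent_identity(self, ltr_baits):
        rng = np.random.default_rng(0)
        bait = ltr_baits.baits["five_prime_fwd"]
        mutated = _mutate(bait, [5, 12], rng)  # interior, so the span is kept
        aln = smith_waterman("ACGT" * 5 + mutated + "TGCA" * 5, bait)
        assert (aln.matches, aln.bait_end - aln.bait_start) == (18, 20)
        assert aln.matches / (aln.bait_end - aln.bait_start) == pytest.approx(0.90)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = random_element(int(rng.integers(1, 41)), rng)
            b = random_element(int(rng.integers(1, 41)), rng)
            aln = smith_waterman(a, b)
            score = aln.score if aln is not None else 0
            assert score == sw_score_bruteforce(a, b)

    def test_tie_breaks_to_smallest_read_start(self, ltr_baits):
        bait = ltr_baits.baits["five_prime_fwd"]
        read = "ACGT" * 3 + bait + "TT" + bait + "ACGT" * 3
        first = smith_waterman(read, bait)
        assert first.read_start == 12
        # determinism: identical calls, identical results
        assert smith_waterman(read, bait) == first


class TestSeedPrefilter:
    def test_pigeonhole_guarantee_for_two_substitutions(self, ltr_baits):
        rng = np.random.default_rng(1)
        bait = ltr_baits.baits["three_prime_fwd"]
        for _ in range(50):
            pos = rng.choice(20, size=2, replace=False)
            read = random_element(40, rng) + _mutate(bait, pos, rng) + random_element(40, rng)
            assert seed_prefilter(read, ltr_baits, max_mismatches=2, min_match_len=20)

    def test_random_read_without_bait_kmer_rejected(self, ltr_baits):
        # k = 20 // (0+1) = 20: requires an exact bait copy
        read = random_element(100, 99)
        assert not seed_prefilter(read, ltr_baits, max_mismatches=0, min_match_len=20)

    def test_prefilter_never_drops_a_detectable_read(self, ltr_baits, hk2_params):
        """Over mutated-bait and random reads, detection implies prefilter pass."""
        rng = np.random.default_rng(2)
        keys = list(ltr_baits.baits)
        for i in range(2_000):
            if i % 2 == 0:
                bait = ltr_baits.baits[keys[i % 4]]
                n_mut = int(rng.integers(0, 3))
                pos = rng.choice(20, size=n_mut, replace=False)
                seq = random_element(35, rng) + _mutate(bait, pos, rng) + random_element(35, rng)
            else:
                seq = random_element(90, rng)
            read = _read(seq, f"p{i}")
            hit = detect_chimera(read, ltr_baits, hk2_params)
            passed = seed_prefilter(
                seq, ltr_baits, hk2_params.max_mismatches, hk2_params.min_match_len
            )
            if hit is not None:
                assert passed, f"prefilter dropped detectable read {i}"


class TestDetectChimera:
    def test_exact_edge_bait_at_read_end(self, ltr_baits, hk2_params):
        bait = ltr_baits.baits["five_prime_fwd"]
        read = _read(random_element(81, 3) + bait)
        hit = detect_chimera(read, ltr_baits, hk2_params)
        assert hit.bait_key == "five_prime_fwd"
        assert hit.identity == 1.0
        assert (hit.read_start, hit.read_end) == (81, 101)

    def test_three_substitutions_rejected_at_ninety_percent(self, ltr_baits, hk2_params):
        # N flanks isolate the bait copy: chance gapped alignments that borrow
        # flanking bases are a legitimate pass and would confound the check
        rng = np.random.default_rng(4)
        bait = ltr_baits.baits["five_prime_fwd"]
        for _ in range(20):
            pos = rng.choice(20, size=3, replace=False)
            read = _read("N" * 50 + _mutate(bait, pos, rng) + "N" * 30)
            assert detect_chimera(read, ltr_baits, hk2_params) is None

    def test_forward_preferred_over_weaker_reverse_complement(self, ltr_baits, hk2_params):
        rng = np.random.default_rng(5)
        fwd = ltr_baits.baits["five_prime_fwd"]
        weak_rc = _mutate(ltr_baits.baits["five_prime_rc"], [3, 9], rng)
        read = _read(random_element(25, 6) + fwd + "AC" + weak_rc + random_element(25, 9))
        hit = detect_chimera(read, ltr_baits, hk2_params)
        assert hit.bait_key == "five_prime_fwd"
        assert hit.identity == 1.0

    def test_equal_scores_resolve_in_fixed_bait_order(self, ltr_baits, hk2_params):
        five = ltr_baits.baits["five_prime_fwd"]
        three = ltr_baits.baits["three_prime_fwd"]
        read = _read(random_element(25, 10) + three + "ACAC" + five + random_element(25, 11))
        hit = detect_chimera(read, ltr_baits, hk2_params)
        assert hit.score == 40  # both exact; tie
        assert hit.bait_key == "five_prime_fwd"

    def test_partial_bait_at_read_end_detected(self, ltr_element, hk2_params):
        # a junction falling near the read end leaves only part of the bait
        bs = make_baits(ltr_element, 30, "ltr30")
        bait = bs.baits["five_prime_fwd"]
        read = _read(random_element(80, 12) + bait[:21])
        hit = detect_chimera(read, bs, hk2_params)
        assert hit is not None
        assert hit.read_end == 101 and hit.match_length == 21


class TestTrimRead:
    def test_left_flank_arithmetic(self, ltr_baits, hk2_params):
        bait = ltr_baits.baits["five_prime_fwd"]
        read = _read(random_element(81, 13) + bait)
        hit = detect_chimera(read, ltr_baits, hk2_params)
        trimmed = trim_read(read, hit, hk2_params)
        assert len(trimmed.host_flank_seq) == 81
        assert len(trimmed.te_portion_seq) == 20
        assert trimmed.flank_side == "left_of_match"

    def test_right_flank_for_three_prime_bait(self, ltr_baits, hk2_params):
        bait = ltr_baits.baits["three_prime_fwd"]
        flank = random_element(60, 14)
        read = _read(bait + flank)
        hit = detect_chimera(read, ltr_baits, hk2_params)
        trimmed = trim_read(read, hit, hk2_params)
        assert trimmed.flank_side == "right_of_match"
        assert trimmed.host_flank_seq == flank
        assert trimmed.te_portion_seq == bait

    def test_reconstruction_covers_the_whole_read(self, ltr_baits, hk2_params):
        for key in ("five_prime_fwd", "five_prime_rc", "three_prime_fwd", "three_prime_rc"):
            bait = ltr_baits.baits[key]
            read = _read(random_element(40, 15) + bait + random_element(41, 16))
            hit = detect_chimera(read, ltr_baits, hk2_params)
            trimmed = trim_read(read, hit, hk2_params)
            if trimmed.flank_side == "left_of_match":
                assert trimmed.host_flank_seq + trimmed.te_portion_seq == read.sequence
            else:
                assert trimmed.te_portion_seq + trimmed.host_flank_seq == read.sequence

    def test_nineteen_base_flank_discarded(self, ltr_baits, hk2_params):
        bait = ltr_baits.baits["five_prime_fwd"]
        read = _read(random_element(19, 17) + bait)
        hit = detect_chimera(read, ltr_baits, hk2_params)
        assert trim_read(read, hit, hk2_params) is None

    def test_read_fully_covered_by_bait_discarded(self, ltr_baits, hk2_params):
        bait = ltr_baits.baits["five_prime_fwd"]
        read = _read(bait)
        hit = detect_chimera(read, ltr_baits, hk2_params)
        assert trim_read(read, hit, hk2_params) is None


class TestCigarPrefilter:
    def _aln(self, cigar, seq_len=101, flag=0):
        return AlignmentRecord(
            read=ReadRecord("r", "A" * seq_len, "I" * seq_len),
            reference_name=None if flag & 0x4 else "ref",
            position=0 if flag & 0x4 else 10,
            cigar=cigar,
            mapq=60,
            flag=flag,
        )

    def test_soft_clipped_read_is_candidate(self, hk2_params):
        assert cigar_prefilter(self._aln("94M7S"), hk2_params)

    def test_perfect_match_is_not(self, hk2_params):
        assert not cigar_prefilter(self._aln("101M"), hk2_params)

    def test_unmapped_and_undefined_cigar_are_candidates(self, hk2_params):
        assert cigar_prefilter(self._aln("*", flag=0x4), hk2_params)
        assert cigar_prefilter(self._aln("*"), hk2_params)


class TestScreenLibrary:
    def test_empty_input_succeeds_with_empty_outputs(self, ltr_baits, hk2_params, tmp_path):
        out = screen_library([], ltr_baits, hk2_params, paired=False, out_prefix=tmp_path / "e")
        assert out.counts["reads_in"] == 0 and out.counts["trimmed"] == 0
        assert out.trimmed_path.read_text() == ""
        assert out.report_path.read_text().startswith("#read_name")

    def test_trimmed_reads_come_from_junction_fragments(self, mini_fixture, mini_pipeline):
        """Every emitted trimmed read's fragment of origin spans a simulated
        host-TE junction (fragment coordinates are encoded in read names)."""
        element_len = len(mini_fixture.element_sequence)
        junctions = set()
        for iv in element_intervals_in_genome(mini_fixture.truths, element_len):
            junctions.update((iv.start, iv.end))
        screen = mini_pipeline["guided"].screen
        n = 0
        for rec in read_fastq(screen.trimmed_path):
            _, start, end, _ = rec.base_name.rsplit(":", 3)
            start, end = int(start), int(end)
            assert any(start < j < end for j in junctions), rec.name
            n += 1
        assert n == screen.counts["trimmed"] > 0

    def test_mate_count_equals_trimmed_count(self, mini_pipeline):
        screen = mini_pipeline["guided"].screen
        assert screen.counts["mates_written"] == screen.counts["trimmed"]
        n_mates = sum(1 for _ in read_fastq(screen.mates_path))
        n_trimmed = sum(1 for _ in read_fastq(screen.trimmed_path))
        n_te = sum(1 for _ in read_fastq(screen.te_path))
        assert n_mates == n_trimmed == n_te

    def test_report_hits_respect_thresholds(self, mini_pipeline, hk2_params):
        with open(mini_pipeline["guided"].screen.report_path) as handle:
            rows = [line.split("\t") for line in handle if not line.startswith("#")]
        assert rows
        for row in rows:
            assert int(row[2]) >= hk2_params.min_match_len
            assert float(row[3]) >= 100 * hk2_params.min_identity - 1e-9

    def test_screening_is_deterministic(self, mini_fixture, ltr_baits, hk2_params, tmp_path):
        from tescreen.baits import baits_from_fasta

        baitset = baits_from_fasta(mini_fixture.element_fasta, 20)[0]
        subset = list(itertools.islice(read_fastq(mini_fixture.reads_fastq), 800))
        outs = []
        for tag in ("a", "b"):
            out = screen_library(
                subset, baitset, hk2_params, paired=True, out_prefix=tmp_path / tag
            )
            outs.append(out)
        assert outs[0].trimmed_path.read_bytes() == outs[1].trimmed_path.read_bytes()
        assert outs[0].report_path.read_bytes() == outs[1].report_path.read_bytes()

    def test_cigar_filter_skips_perfectly_mapped_reads(self, ltr_baits, tmp_path):
        params = ScreenParams(
            min_match_len=20, min_identity=0.90, min_trimmed_len=20, cigar_filter_enabled=True
        )
        bait = ltr_baits.baits["five_prime_fwd"]
        seq = random_element(81, 18) + bait
        perfect = AlignmentRecord(
            read=ReadRecord("perfect", seq, "I" * 101),
            reference_name="ref", position=1, cigar="101M", mapq=60, flag=0,
        )
        clipped = AlignmentRecord(
            read=ReadRecord("clipped", seq, "I" * 101),
            reference_name="ref", position=1, cigar="81M20S", mapq=60, flag=0,
        )
        out = screen_library(
            [perfect, clipped], ltr_baits, params, paired=False, out_prefix=tmp_path / "c"
        )
        assert out.counts["trimmed"] == 1
        assert out.counts["discarded_cigar_filter"] == 1
        report = out.report_path.read_text()
        assert "clipped" in report and "perfect" not in report
        assert "\tref\t1\t60\t81M20S" in report  # original mapping retained
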