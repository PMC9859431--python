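"""End clustering, TIS/TTS inference, termination, isoforms, degradation."""

import numpy as np
import pytest

from mitotx import fixtures
from mitotx.boundaries import (
    call_isoforms,
    cluster_ends,
    cluster_positions,
    degradation_direction,
    detect_termination,
    infer_tis,
    infer_tts,
)
from mitotx.classify import CoverageTrack, build_coverage
from mitotx.core_io import (
    GeneFeature,
    GenomeSpan,
    MitoAnnotation,
    TranscriptAlignment,
)

L = fixtures.GENOME_LENGTH


def aln(rid, start, end, orientation="plus", wraps=False):
    return TranscriptAlignment(rid, orientation,
                               GenomeSpan(start, end, orientation, wraps))


class TestClustering:
    def test_greedy_collapse_and_min_support(self):
        clusters = cluster_positions([100] * 5 + [101] * 2 + [300],
                                     cluster_tol=3, min_support=2)
        assert clusters == [(100, 7, 1)]

    def test_all_distinct_below_support(self):
        assert cluster_positions([10, 20, 30], 3, min_support=2) == []

    def test_noisy_ends_collapse_to_mode(self):
        rng = np.random.default_rng(2)
        mu = 5000
        ends = (mu + rng.integers(-1, 2, size=200)).tolist()
        clusters = cluster_positions(ends, 3, min_support=2)
        assert len(clusters) == 1
        pos, support, spread = clusters[0]
        # modal position equals the true mode of the drawn sample
        vals, counts = np.unique(ends, return_counts=True)
        assert pos == vals[counts.argmax()]
        assert support == 200 and spread <= 3


class TestTIS:
    def test_plus_tis_from_published_end_set(self, refined_ann):
        cr = refined_ann.get("CR").span
        clusters = cluster_ends(fixtures.cr_alignments(), "plus",
                                "five_prime")
        call = infer_tis(clusters, cr, L)
        assert call.position == 15377 and call.support >= 2

    def test_minus_tis_needs_two_supporting_reads(self, refined_ann):
        cr = refined_ann.get("CR").span
        clusters = cluster_ends(fixtures.cr_alignments(), "minus",
                                "five_prime")
        call = infer_tis(clusters, cr, L)
        assert call.position == 15189 and call.support == 2

    def test_single_supported_cluster_inside_cr(self, refined_ann):
        cr = refined_ann.get("CR").span
        alns = [aln(f"r{i}", 15800, 16100) for i in range(10)]
        call = infer_tis(cluster_ends(alns, "plus", "five_prime"), cr, L)
        assert call.position == 15800 and call.support == 10

    def test_no_qualifying_cluster_returns_absent(self, refined_ann):
        cr = refined_ann.get("CR").span
        alns = [aln("r", 100, 500)]  # 5' end outside CR
        assert infer_tis(cluster_ends(alns, "plus", "five_prime"), cr, L) is None


class TestTTS:
    def test_wrap_spanning_antisense_cr_transcript(self, refined_ann):
        cr = refined_ann.get("CR").span
        call = infer_tts(fixtures.cr_alignments(), cr, "minus", L)
        assert call.position == 15406

    def test_no_read_reaching_cr(self, refined_ann):
        cr = refined_ann.get("CR").span
        assert infer_tts([aln("r", 100, 500)], cr, "plus", L) is None

    def test_furthest_penetration_wins(self, refined_ann):
        cr = refined_ann.get("CR").span
        alns = [
            TranscriptAlignment("a", "minus",
                                GenomeSpan(15400, 72, "minus", wraps=True)),
            TranscriptAlignment("b", "minus",
                                GenomeSpan(15406, 72, "minus", wraps=True)),
        ]
        # deeper penetration along minus transcription = smaller coordinate
        assert infer_tts(alns, cr, "minus", L).position == 15400

    def test_lncrna_initiated_inside_cr_not_a_witness(self, refined_ann):
        cr = refined_ann.get("CR").span
        alns = [aln("x", 14901, 15189, "minus")]  # 5' end inside CR
        assert infer_tts(alns, cr, "minus", L) is None


class TestTermination:
    def toy(self):
        ann = MitoAnnotation(300, [
            GeneFeature("A", "PCG", GenomeSpan(1, 100)),
            GeneFeature("B", "PCG", GenomeSpan(101, 200)),
            GeneFeature("C", "PCG", GenomeSpan(201, 300)),
        ])
        return ann

    def test_terminator_on_coverage_collapse(self, sim_bundle):
        track = build_coverage(sim_bundle["alignments"], L)
        calls = detect_termination(track, sim_bundle["annotation"])
        assert [(c.orientation, c.junction, c.kind) for c in calls] == [
            ("plus", ("trnS2", "ND1"), "terminator")
        ]

    def test_uniform_coverage_silent(self):
        ann = self.toy()
        track = CoverageTrack(np.full(300, 50), np.zeros(300, dtype=int))
        assert detect_termination(track, ann) == []

    def test_attenuator_between_thresholds(self):
        ann = self.toy()
        plus = np.concatenate([np.full(100, 100), np.full(100, 20),
                               np.full(100, 20)])
        track = CoverageTrack(plus, np.zeros(300, dtype=int))
        calls = detect_termination(track, ann, drop_ratio=0.25)
        assert [(c.junction, c.kind) for c in calls] == [
            (("A", "B"), "attenuator")
        ]


class TestIsoforms:
    def isoform_reads(self, per=40, noise=10, seed=0):
        rng = np.random.default_rng(seed)
        alns = []
        i = 0
        for f5, f3 in fixtures.LRRNA_ISOFORMS:
            for _ in range(per):
                alns.append(aln(f"r{i}", f3, f5, "minus"))
                i += 1
        for _ in range(noise):
            f5 = int(rng.integers(12600, 13400))
            alns.append(aln(f"n{i}", 12501, f5, "minus"))
            i += 1
        return alns

    def test_three_lrrna_isoforms_recovered(self):
        calls = call_isoforms(self.isoform_reads(), "lrRNA")
        assert len(calls) == 3
        assert sorted(c.five_prime for c in calls) == [13484, 13498, 13687]
        assert all(c.three_prime == 12501 for c in calls)
        assert all(c.support >= 40 for c in calls)

    def test_identical_reads_give_single_isoform(self):
        alns = [aln(f"r{i}", 12501, 13687, "minus") for i in range(20)]
        assert len(call_isoforms(alns, "lrRNA")) == 1

    def test_uniform_noise_calls_nothing(self):
        rng = np.random.default_rng(1)
        alns = [aln(f"r{i}", 12501, int(rng.integers(12600, 13700)), "minus")
                for i in range(100)]
        assert call_isoforms(alns, "lrRNA", min_isoform_support=5) == []

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_recovers_k_planted_isoforms(self, k):
        positions = [13000 + 120 * i for i in range(k)]
        threshold = 5
        alns = []
        i = 0
        for pos in positions:
            for _ in range(2 * threshold):
                alns.append(aln(f"r{i}", 12501, pos, "minus"))
                i += 1
        calls = call_isoforms(alns, "rRNA", min_isoform_support=threshold)
        assert sorted(c.five_prime for c in calls) == positions


class TestDegradation:
    gene = GeneFeature("lrRNA", "rRNA", GenomeSpan(12501, 13774, "minus"))

    def reads(self, n5, n3, ncomplete=5):
        alns = [aln(f"c{i}", 12501, 13774, "minus") for i in range(ncomplete)]
        # minus gene: 5'-truncated reads lose high coordinates
        alns += [aln(f"f{i}", 12501, 13700, "minus") for i in range(n5)]
        alns += [aln(f"t{i}", 12560, 13774, "minus") for i in range(n3)]
        return alns

    def test_dominant_5prime_truncation(self):
        assert degradation_direction(self.reads(80, 5), self.gene,
                                     genome_length=L) == "five_to_three"

    def test_dominant_3prime_truncation(self):
        assert degradation_direction(self.reads(5, 80), self.gene,
                                     genome_length=L) == "three_to_five"

    def test_balanced_counts_undetermined(self):
        assert degradation_direction(self.reads(10, 10), self.gene,
                                     genome_length=L) == "undetermined"

    def test_too_few_truncated_reads_undetermined(self):
        assert degradation_direction(self.reads(5, 1), self.gene,
                                     genome_length=L) == "undetermined"
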