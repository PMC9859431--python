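"""Transcript-guided boundary refinement against the printed gene table."""

import numpy as np
import pytest

from mitotx import fixtures
from mitotx.core_io import GenomeSpan, TranscriptAlignment
from mitotx.refine import (
    EndEvidence,
    collect_end_evidence,
    derive_cr,
    refine_annotation,
    refine_pcg_3prime,
    refine_pcg_5prime,
    refine_rrna,
    validate_annotation,
)
from mitotx.synthetic import SimConfig, simulate_genome

L = fixtures.GENOME_LENGTH


@pytest.fixture(scope="module")
def genome():
    seq, _, _ = simulate_genome(SimConfig(seed=1))
    return seq


def ev3(gene, pos, n=20, polyA=True):
    return [EndEvidence(gene, "three_prime", pos, n, polyA)]


def ev5(gene, pos, n=20):
    return [EndEvidence(gene, "five_prime", pos, n)]


class TestPCG3Prime:
    @pytest.mark.parametrize(
        "gene,pos,new_span,stop,length",
        [
            ("ND2", 1204, (229, 1204), "U", 976),
            ("COX3", 5453, (4666, 5453), "UA", 788),
            ("ATP6", 4665, (3996, 4665), "U", 670),
        ],
    )
    def test_incomplete_stop_codons(self, dna_ann, genome, gene, pos,
                                    new_span, stop, length):
        new = refine_pcg_3prime(dna_ann.get(gene), ev3(gene, pos), genome)
        assert (new.span.start, new.span.end) == new_span
        assert new.stop_codon == stop
        assert new.span.end - new.span.start + 1 == length

    def test_unchanged_when_dominant_end_is_annotated_end(self, dna_ann, genome):
        cytb = dna_ann.get("CYTB")
        new = refine_pcg_3prime(cytb, ev3("CYTB", 11418), genome)
        assert new.span == cytb.span and new.stop_codon == "UAA"

    def test_frame_inconsistent_end_leaves_gene_unchanged(self):
        from mitotx.core_io import GeneFeature, MitoAnnotation

        # gene ATA GGG CCC TAA on a toy genome; a dominant end at position 8
        # leaves remnant "CC", which polyadenylation cannot complete to UAA
        toy = "ATAGGGCCCTAAGGGGG"
        gene = GeneFeature("g", "PCG", GenomeSpan(1, 12), "AUA", "UAA")
        new = refine_pcg_3prime(gene, ev3("g", 8), toy)
        assert new.span == gene.span

    def test_boundary_never_extends_past_dna_stop(self, dna_ann, genome):
        nd2 = dna_ann.get("ND2")
        new = refine_pcg_3prime(nd2, ev3("ND2", 1300), genome)
        assert new.span.end <= 1206

    def test_no_polya_backed_evidence_is_ignored(self, dna_ann, genome):
        nd2 = dna_ann.get("ND2")
        new = refine_pcg_3prime(nd2, ev3("ND2", 1204, polyA=False), genome)
        assert new.span == nd2.span


class TestPCG5Prime:
    def test_nd3_moves_to_downstream_start_codon(self, dna_ann, genome):
        new = refine_pcg_5prime(dna_ann.get("ND3"), ev5("ND3", 5519), genome)
        assert (new.span.start, new.span.end) == (5519, 5872)
        assert new.start_codon == "AUA"
        assert new.span.end - new.span.start + 1 == 354

    def test_minus_strand_nd1(self, dna_ann, genome):
        new = refine_pcg_5prime(dna_ann.get("ND1"), ev5("ND1", 12433), genome)
        assert (new.span.start, new.span.end) == (11510, 12433)
        assert new.start_codon == "AUG"
        assert new.span.end - new.span.start + 1 == 924

    def test_unchanged_when_dominant_equals_current(self, dna_ann, genome):
        cox1 = dna_ann.get("COX1")
        new = refine_pcg_5prime(cox1, ev5("COX1", 1407), genome)
        assert new.span == cox1.span

    def test_no_start_codon_in_window_warns(self, dna_ann, genome):
        nd3 = dna_ann.get("ND3")
        with pytest.warns(UserWarning, match="start codon"):
            new = refine_pcg_5prime(nd3, ev5("ND3", 5520), genome)
        assert new.span == nd3.span


class TestRRNA:
    def test_srrna_5prime_cluster_support_273(self, dna_ann):
        ev = [EndEvidence("srRNA", "five_prime", 14661, 273)]
        new = refine_rrna(dna_ann.get("srRNA"), ev)
        assert (new.span.start, new.span.end) == (13842, 14661)
        assert new.span.end - new.span.start + 1 == 820

    def test_lrrna_unchanged_by_concordant_evidence(self, dna_ann):
        ev = [EndEvidence("lrRNA", "five_prime", 13774, 4000),
              EndEvidence("lrRNA", "three_prime", 12501, 4000)]
        new = refine_rrna(dna_ann.get("lrRNA"), ev)
        assert (new.span.start, new.span.end) == (12501, 13774)
        assert new.span.end - new.span.start + 1 == 1274

    def test_empty_evidence_warns_and_keeps(self, dna_ann):
        with pytest.warns(UserWarning):
            new = refine_rrna(dna_ann.get("srRNA"), [])
        assert new.span == dna_ann.get("srRNA").span

    def test_below_min_support_keeps_boundary(self, dna_ann):
        ev = [EndEvidence("srRNA", "five_prime", 14661, 2)]
        with pytest.warns(UserWarning, match="support"):
            new = refine_rrna(dna_ann.get("srRNA"), ev, min_support=3)
        assert new.span == dna_ann.get("srRNA").span


class TestControlRegion:
    def test_cr_from_dna_annotation(self, dna_ann):
        ann = dna_ann.copy()
        cr = derive_cr(ann)
        assert (cr.span.start, cr.span.end) == (14653, 16214)
        assert cr.span.length(L) == 1562

    def test_cr_after_srrna_refinement(self, dna_ann):
        ann = dna_ann.copy()
        ev = [EndEvidence("srRNA", "five_prime", 14661, 273)]
        ann.replace_feature(refine_rrna(ann.get("srRNA"), ev))
        cr = derive_cr(ann)
        assert cr.span.length(L) == 1553

    def test_toy_circle(self):
        from mitotx.core_io import GeneFeature, MitoAnnotation

        ann = MitoAnnotation(100, [
            GeneFeature("g1", "PCG", GenomeSpan(1, 50)),
            GeneFeature("g2", "PCG", GenomeSpan(51, 90)),
        ])
        cr = derive_cr(ann)
        assert (cr.span.start, cr.span.end) == (91, 100)
        assert cr.span.length(100) == 10

    def test_tied_gaps_rejected(self):
        from mitotx.core_io import GeneFeature, MitoAnnotation

        ann = MitoAnnotation(100, [
            GeneFeature("g1", "PCG", GenomeSpan(1, 40)),
            GeneFeature("g2", "PCG", GenomeSpan(51, 90)),
        ])
        with pytest.raises(ValueError, match="equally largest"):
            derive_cr(ann)


class TestOverlapValidation:
    def test_five_overlaps_disappear_after_refinement(self, dna_ann,
                                                      refined_ann):
        report = validate_annotation(refined_ann, dna_annotation=dna_ann)
        assert report.residual_overlaps == []
        assert set(report.removed_overlaps) == {
            ("ND2", "trnW"), ("ATP6", "COX3"), ("COX3", "trnG"),
            ("trnG", "ND3"), ("ND1", "trnL1"),
        }

    def test_dna_annotation_has_five_same_strand_overlaps(self, dna_ann):
        report = validate_annotation(dna_ann)
        assert len(report.residual_overlaps) == 5

    def test_single_gene_annotation_clean(self):
        from mitotx.core_io import GeneFeature, MitoAnnotation

        ann = MitoAnnotation(100, [GeneFeature("g", "PCG", GenomeSpan(1, 60))])
        assert validate_annotation(ann).residual_overlaps == []


class TestFullRefinement:
    def make_evidence(self, refined_ann):
        ev = []
        for f in refined_ann.genes():
            s = f.span
            ev.append(EndEvidence(f.name, "five_prime", s.five_prime, 10))
            ev.append(EndEvidence(f.name, "three_prime", s.three_prime, 10,
                                  polyA_backed=True))
        return ev

    def test_recovers_refined_table_from_dna_annotation(self, dna_ann,
                                                        refined_ann, genome):
        ev = self.make_evidence(refined_ann)
        out, report = refine_annotation(dna_ann, ev, genome)
        for f in refined_ann.genes():
            assert out.get(f.name).span == f.span, f.name
        assert out.get("CR").span.length(L) == 1553
        assert report.residual_overlaps == []

    def test_refinement_is_idempotent(self, dna_ann, refined_ann, genome):
        ev = self.make_evidence(refined_ann)
        once, _ = refine_annotation(dna_ann, ev, genome)
        twice, rep2 = refine_annotation(once, ev, genome)
        for a, b in zip(once.features, twice.features):
            assert a.span == b.span and a.stop_codon == b.stop_codon
        assert rep2.changes == []

    def test_pcg_length_mod3_consistent_with_stop(self, dna_ann, refined_ann,
                                                  genome):
        ev = self.make_evidence(refined_ann)
        out, _ = refine_annotation(dna_ann, ev, genome)
        from mitotx.refine import START_CODONS

        for f in out.genes():
            if f.category != "PCG":
                continue
            length = f.span.end - f.span.start + 1
            assert f.start_codon in START_CODONS
            assert length % 3 == {3: 0, 1: 1, 2: 2}[len(f.stop_codon)]

    def test_boundary_recovery_from_error_free_reads(self, dna_ann,
                                                     refined_ann, genome):
        # five error-free mature reads per gene suffice to recover every
        # boundary exactly
        alns = []
        for f in refined_ann.genes():
            for i in range(5):
                alns.append(TranscriptAlignment(
                    f"{f.name}_{i}", f.orientation, f.span,
                    tail3="A" * 8))
        ev = collect_end_evidence(alns, dna_ann)
        out, _ = refine_annotation(dna_ann, ev, genome)
        for f in refined_ann.genes():
            assert out.get(f.name).span == f.span, f.name
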