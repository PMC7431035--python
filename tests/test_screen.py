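"""Conservation screen: windows, criteria, repeats, reciprocity, refinement."""

import numpy as np
import pytest

from crescan.align import LocalAlignment
from crescan.io_formats import AnnotationSet, GenomeLocus, HomologyTable, Interval
from crescan.screen import (
    CandidateCRE,
    CriteriaThresholds,
    Window,
    apply_criteria,
    candidate_search,
    detect_repeats,
    find_orfs,
    homolog_windows,
    mask_coding,
    reciprocal_uniqueness,
    refine,
)
from crescan.synthetic import SyntheticSpec, evolve_sequence, random_sequence

from conftest import random_dna


def _locus(seq, chrom="chr", species="S"):
    return GenomeLocus(species, chrom, 0, len(seq), "+", seq, chrom)


def _gene_ann(chrom, start, end, name):
    return AnnotationSet([Interval(chrom, start, end, "+", "gene", name)])


class TestHomologWindows:
    def test_zero_flank_equals_gene_span(self):
        la, lb = _locus("A" * 1000, "cA"), _locus("C" * 800, "cB")
        ann_a, ann_b = _gene_ann("cA", 100, 200, "gA"), _gene_ann("cB", 300, 500, "gB")
        hom = HomologyTable([("gA", ["gB"])])
        ((wa, wb),) = homolog_windows(la, lb, ann_a, ann_b, hom, flank=0)
        assert (wa.start, wa.end) == (100, 200)
        assert (wb.start, wb.end) == (300, 500)

    def test_one_to_many_gives_two_pairs(self):
        la, lb = _locus("A" * 500, "cA"), _locus("C" * 900, "cB")
        ann_a = _gene_ann("cA", 10, 50, "gA")
        ann_b = AnnotationSet([
            Interval("cB", 10, 60, "+", "gene", "gB1"),
            Interval("cB", 700, 800, "+", "gene", "gB2"),
        ])
        hom = HomologyTable([("gA", ["gB1", "gB2"])])
        pairs = homolog_windows(la, lb, ann_a, ann_b, hom, flank=0)
        assert [wb.gene for _wa, wb in pairs] == ["gB1", "gB2"]

    def test_flank_clipped_to_locus(self):
        la, lb = _locus("A" * 300, "cA"), _locus("C" * 300, "cB")
        ann_a, ann_b = _gene_ann("cA", 100, 150, "gA"), _gene_ann("cB", 100, 150, "gB")
        hom = HomologyTable([("gA", ["gB"])])
        ((wa, wb),) = homolog_windows(la, lb, ann_a, ann_b, hom, flank=10_000)
        assert (wa.start, wa.end) == (0, 300)
        assert (wb.start, wb.end) == (0, 300)

    def test_unresolvable_gene_named(self):
        la, lb = _locus("A" * 100, "cA"), _locus("C" * 100, "cB")
        hom = HomologyTable([("ghost", ["gB"])])
        with pytest.raises(ValueError, match="ghost"):
            homolog_windows(la, lb, AnnotationSet(), _gene_ann("cB", 0, 10, "gB"), hom)


class TestCandidateSearch:
    def test_planted_element_recovered(self, gapped_params, rng):
        elem = random_dna(150, rng)
        seq_a = random_dna(400, rng) + elem + random_dna(400, rng)
        elem_b = evolve_sequence(elem, 0.85, 0.05, 1)
        seq_b = random_dna(300, rng) + elem_b + random_dna(500, rng)
        wa = Window(_locus(seq_a, "cA"), 0, len(seq_a), "gA")
        wb = Window(_locus(seq_b, "cB"), 0, len(seq_b), "gB")
        cands = candidate_search(wa, wb, params=gapped_params)
        assert cands, "no candidate found"
        top = cands[0]
        overlap = max(0, min(top.query_end, 550) - max(top.query_start, 400))
        assert overlap >= 75
        assert top.linked_gene_pair == ("gA", "gB")
        assert top.alignment.evalue < 1e-6

    def test_unrelated_windows_high_min_score_empty(self, gapped_params, rng):
        wa = Window(_locus(random_dna(300, rng), "cA"), 0, 300, "gA")
        wb = Window(_locus(random_dna(300, rng), "cB"), 0, 300, "gB")
        assert candidate_search(wa, wb, params=gapped_params, min_score=500) == []

    def test_minus_strand_element_reported_on_minus(self, gapped_params, rng):
        from crescan.align import revcomp

        elem = random_dna(150, rng)
        seq_a = random_dna(200, rng) + elem + random_dna(200, rng)
        seq_b = random_dna(250, rng) + revcomp(evolve_sequence(elem, 0.9, 0.0, 2)) + random_dna(150, rng)
        wa = Window(_locus(seq_a, "cA"), 0, len(seq_a), "gA")
        wb = Window(_locus(seq_b, "cB"), 0, len(seq_b), "gB")
        cands = candidate_search(wa, wb, params=gapped_params)
        top = cands[0]
        assert top.hit_strand == "-"
        # hit interval still reported in forward coordinates
        assert 200 <= top.hit_start < top.hit_end <= 450


class TestMaskCoding:
    def _cand(self, start, end, chrom="cA"):
        aln = LocalAlignment(0, end - start, 0, end - start, "A", "A", 10)
        return CandidateCRE("c", chrom, start, end, "cB", 0, end - start, "+", aln)

    def test_inside_exon_is_coding(self):
        ann = AnnotationSet([Interval("cA", 100, 220, "+", "exon", "e")])
        assert mask_coding(self._cand(120, 180), ann) is False

    def test_intron_without_orf_is_noncoding(self, rng):
        ann = AnnotationSet([Interval("cA", 500, 620, "+", "exon", "e")])
        cand = self._cand(100, 260)
        assert mask_coding(cand, ann, query_seq=random_dna(160, rng)) is True

    def test_single_base_exon_overlap_vetoes_by_default(self):
        ann = AnnotationSet([Interval("cA", 199, 320, "+", "exon", "e")])
        assert mask_coding(self._cand(100, 200), ann) is False

    def test_orf_veto_without_annotation(self):
        orf = "ATG" + "GCT" * 100 + "TAA"  # 306 bp ORF
        seq = "TTTT" + orf + "TTTT"
        cand = self._cand(0, len(seq))
        assert mask_coding(cand, AnnotationSet(), query_seq=seq) is False

    def test_find_orfs_both_strands(self):
        from crescan.align import revcomp

        orf = "ATG" + "GCA" * 99 + "TGA"
        fwd = find_orfs("TT" + orf + "AA", min_length=300)
        assert any(s == "+" for _s, _e, s in fwd)
        rev = find_orfs("TT" + revcomp(orf) + "AA", min_length=300)
        assert any(s == "-" for _s, _e, s in rev)


class TestDetectRepeats:
    def test_homopolymer_fully_flagged(self):
        ivs = detect_repeats("A" * 100)
        assert len(ivs) == 1
        s, e = ivs[0]
        assert s == 0 and e == 100

    def test_tandem_dinucleotide_flagged(self):
        ivs = detect_repeats("AT" * 50)
        assert ivs and ivs[0][1] - ivs[0][0] >= 90

    def test_random_sequence_rarely_flagged(self):
        fracs = []
        for seed in range(20):
            seq = random_sequence(1000, np.random.default_rng(seed))
            covered = sum(e - s for s, e in detect_repeats(seq))
            fracs.append(covered / 1000)
        assert float(np.mean(fracs)) <= 0.05

    def test_window_precondition(self):
        with pytest.raises(ValueError, match="16"):
            detect_repeats("ACGT" * 10, window=8)


class TestApplyCriteria:
    def _cand_with(self, identity, n_columns, ev, qseq=None, start=1000):
        n_id = int(identity * n_columns + 1e-9)
        ga = "A" * n_columns
        gb = "A" * n_id + "C" * (n_columns - n_id)
        aln = LocalAlignment(0, n_columns, 0, n_columns, ga, gb, 100)
        aln.n_identical, aln.n_columns, aln.identity = n_id, n_columns, n_id / n_columns
        aln.evalue = ev
        cand = CandidateCRE(
            "c", "cA", start, start + n_columns, "cB", 0, n_columns, "+", aln,
            linked_gene_pair=("gA", "gB"),
        )
        if qseq is None:
            qseq = "".join(
                np.random.default_rng(99).choice(list("ACGT"), size=n_columns)
            )
        cand._query_seq = qseq
        return cand

    def test_all_four_pass(self):
        cand = self._cand_with(0.70, 60, 1e-3)
        apply_criteria(cand, CriteriaThresholds(), AnnotationSet())
        assert cand.criteria.all_pass()

    def test_identity_just_below_cutoff_fails(self):
        cand = self._cand_with(0.619, 100, 1e-3)
        apply_criteria(cand, CriteriaThresholds(), AnnotationSet())
        assert cand.criteria.identity_length_evalue is False

    def test_identity_at_cutoff_passes_inclusive(self):
        cand = self._cand_with(0.62, 100, 1e-3)
        apply_criteria(cand, CriteriaThresholds(), AnnotationSet())
        assert cand.criteria.identity_length_evalue is True

    def test_short_alignment_fails_length(self):
        cand = self._cand_with(0.80, 54, 1e-3)
        apply_criteria(cand, CriteriaThresholds(), AnnotationSet())
        assert cand.criteria.identity_length_evalue is False

    def test_weak_evalue_fails(self):
        cand = self._cand_with(0.80, 100, 0.5)
        apply_criteria(cand, CriteriaThresholds(), AnnotationSet())
        assert cand.criteria.identity_length_evalue is False

    def test_repeat_dominated_candidate_fails_criterion4(self):
        cand = self._cand_with(0.9, 60, 1e-5, qseq="A" * 60)
        apply_criteria(cand, CriteriaThresholds(), AnnotationSet())
        assert cand.criteria.nonrepetitive is False

    def test_missing_evalue_is_an_error(self):
        cand = self._cand_with(0.7, 60, None)
        with pytest.raises(ValueError, match="E-value"):
            apply_criteria(cand, CriteriaThresholds(), AnnotationSet())


class TestReciprocalUniqueness:
    def _setup(self, rng, extra_copy=False):
        elem = random_dna(150, rng)
        seq_b = random_dna(500, rng) + evolve_sequence(elem, 0.9, 0.0, 1) + random_dna(2000, rng)
        if extra_copy:
            # far from the homolog window (which ends at 1500)
            seq_b = seq_b[:2200] + evolve_sequence(elem, 0.9, 0.0, 2) + seq_b[2350:]
        locus_b = _locus(seq_b, "cB")
        win_b = Window(locus_b, 0, 1500, "gB")
        aln = LocalAlignment(0, 150, 0, 150, elem, elem, 750)
        aln.evalue = 1e-20
        cand = CandidateCRE("c", "cA", 0, 150, "cB", 500, 650, "+", aln,
                            linked_gene_pair=("gA", "gB"))
        cand._query_seq = elem
        return cand, locus_b, win_b

    def test_single_copy_is_unique(self, rng, gapped_params):
        cand, locus_b, win_b = self._setup(rng)
        assert reciprocal_uniqueness(cand, [locus_b], win_b, params=gapped_params) is True

    def test_second_distant_copy_flips_false(self, rng, gapped_params):
        cand, locus_b, win_b = self._setup(rng, extra_copy=True)
        assert reciprocal_uniqueness(cand, [locus_b], win_b, params=gapped_params) is False

    def test_vacuous_uniqueness_warns_via_log(self, rng, gapped_params, caplog):
        cand, locus_b, win_b = self._setup(rng)
        cand._query_seq = random_dna(60, rng)  # matches nothing at criteria level
        import logging

        with caplog.at_level(logging.WARNING, logger="crescan.screen"):
            assert reciprocal_uniqueness(cand, [locus_b], win_b, params=gapped_params) is True
        assert any("vacuity" in r.message for r in caplog.records)


class TestRefine:
    def test_identical_intervals_identity_one(self):
        aln = LocalAlignment(0, 30, 0, 30, "A" * 30, "A" * 30, 150)
        cand = CandidateCRE("c", "cA", 0, 30, "cB", 0, 30, "+", aln)
        cand._query_seq = "ACGTT" * 6
        cand._hit_seq = "ACGTT" * 6
        assert refine(cand) == 1.0
        assert cand.refined_alignment is not None

    def test_refined_close_to_local_identity_on_planted(self, rng):
        elem = random_dna(150, rng)
        elem_b = evolve_sequence(elem, 0.8, 0.05, 3)
        from crescan.align import smith_waterman

        local = smith_waterman(elem, elem_b)
        aln = LocalAlignment(0, 150, 0, len(elem_b), elem, elem_b, 1)
        cand = CandidateCRE("c", "cA", 0, 150, "cB", 0, len(elem_b), "+", aln)
        cand._query_seq, cand._hit_seq = elem, elem_b
        refined = refine(cand)
        assert refined == pytest.approx(local.identity, abs=0.05)

    def test_refinement_never_changes_verdict(self):
        from crescan.screen import Criteria

        aln = LocalAlignment(0, 30, 0, 30, "A" * 30, "A" * 30, 150)
        cand = CandidateCRE("c", "cA", 0, 30, "cB", 0, 30, "+", aln)
        cand._query_seq = cand._hit_seq = "ACGTT" * 6
        cand.criteria = Criteria(True, True, True, True)
        cand.reciprocal_unique = True
        before = cand.verdict
        refine(cand)
        assert cand.verdict == before


class TestScreenEndToEnd:
    def test_synthetic_pair_recovery(self, gapped_params):
        from crescan.pipeline import evaluate_pair

        res = evaluate_pair(SyntheticSpec(seed=7), params=gapped_params)
        assert res["n_recovered"] == res["n_truth"] == 1

    def test_low_identity_element_not_passing_criterion2(self, gapped_params):
        """Elements at realized identity ~0.55 should fail the identity gate."""
        from crescan.pipeline import evaluate_pair

        spec = SyntheticSpec(target_identity=0.55, background_identity=0.0, seed=3)
        res = evaluate_pair(spec, params=gapped_params)
        assert res["n_recovered"] == 0
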