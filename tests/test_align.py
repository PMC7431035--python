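"""Alignment core: oracle equivalence, declumping, identity conventions."""

import numpy as np
import pytest

from crescan.align import (
    LocalAlignment,
    ScoringScheme,
    alignment_identity,
    needleman_wunsch,
    smith_waterman,
    waterman_eggert,
)

from conftest import random_dna


def naive_affine_dp(a, b, sc, local):
    """Independent full-matrix three-state DP (test oracle)."""
    NEG = -(10**9)
    n, m = len(a), len(b)
    go, ge = sc.gap_open + sc.gap_extend, sc.gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    if not local:
        for j in range(1, m + 1):
            H[0][j] = -(go + (j - 1) * ge)
        for i in range(1, n + 1):
            H[i][0] = -(go + (i - 1) * ge)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            s = sc.match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else sc.mismatch
            h = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if local:
                h = max(h, 0)
            H[i][j] = h
            best = max(best, h)
    return best if local else H[n][m]


class TestSmithWaterman:
    def test_identical_sequences(self):
        aln = smith_waterman("ACGT", "ACGT", ScoringScheme(5, -4, 10, 1))
        assert aln.score == 20
        assert aln.identity == 1.0
        assert aln.a_interval == (0, 4) and aln.b_interval == (0, 4)

    def test_classic_linear_gap_instance(self):
        # well-known worked example with match +3, mismatch -3, linear gap -2
        sc = ScoringScheme(match=3, mismatch=-3, gap_open=0, gap_extend=2)
        aln = smith_waterman("TGTTACGG", "GGTTGACTA", sc)
        assert aln.score == 13

    def test_all_mismatch_returns_empty(self):
        aln = smith_waterman("AAAA", "TTTT", ScoringScheme(1, -1, 2, 1))
        assert aln.score == 0
        assert aln.n_columns == 0
        assert aln.a_gapped == "" and aln.b_gapped == ""

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_oracle_equivalence_random_instances(self):
        """Exact DP equals an independent naive full-matrix DP, 200 instances."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = "".join(rng.choice(list("ACGTN"), size=rng.integers(1, 65)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 65)))
            sc = ScoringScheme(
                match=int(rng.integers(1, 6)),
                mismatch=-int(rng.integers(0, 6)),
                gap_open=int(rng.integers(0, 13)),
                gap_extend=int(rng.integers(1, 5)),
            )
            assert smith_waterman(a, b, sc).score == naive_affine_dp(a, b, sc, True)
            assert needleman_wunsch(a, b, sc).score == naive_affine_dp(a, b, sc, False)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_dna(50, rng), random_dna(60, rng)
            sc = ScoringScheme()
            assert smith_waterman(a, b, sc).score == smith_waterman(b, a, sc).score
            assert needleman_wunsch(a, b, sc).score == needleman_wunsch(b, a, sc).score

    def test_score_reconstruction(self, rng):
        for _ in range(20):
            a, b = random_dna(80, rng), random_dna(80, rng)
            sc = ScoringScheme()
            aln = smith_waterman(a, b, sc)
            if aln.n_columns:
                assert aln.rescore(sc) == aln.score
            g = needleman_wunsch(a, b, sc)
            assert g.rescore(sc) == g.score


class TestNeedlemanWunsch:
    def test_identical(self):
        aln = needleman_wunsch("ACGT", "ACGT")
        assert aln.identity == 1.0
        assert "-" not in aln.a_gapped + aln.b_gapped

    def test_single_deletion_gives_one_gap_column(self):
        aln = needleman_wunsch("ACGT", "ACG")
        assert aln.b_gapped.count("-") == 1
        assert aln.a_gapped.count("-") == 0
        assert aln.n_columns == 4

    def test_matches_oracle_on_long_random(self, rng):
        for _ in range(10):
            a, b = random_dna(200, rng), random_dna(200, rng)
            sc = ScoringScheme()
            assert needleman_wunsch(a, b, sc).score == naive_affine_dp(a, b, sc, False)


class TestWatermanEggert:
    def test_identical_single(self):
        res = waterman_eggert("ACGTACGT", "ACGTACGT", k_max=1)
        assert len(res) == 1
        assert res[0].identity == 1.0
        assert res[0].a_interval == (0, 8)

    def test_two_planted_copies_found_disjoint(self, rng):
        core = random_dna(30, rng)
        b = random_dna(40, rng) + core + random_dna(50, rng) + core + random_dna(40, rng)
        res = waterman_eggert(core, b, k_max=2, min_score=100)
        assert len(res) == 2
        (s1, e1), (s2, e2) = sorted(r.b_interval for r in res)
        assert e1 <= s2, "declumped alignments must not overlap in b"
        assert {(s1, e1), (s2, e2)} == {(40, 70), (120, 150)}

    def test_high_min_score_empty(self, rng):
        a, b = random_dna(50, rng), random_dna(50, rng)
        best = smith_waterman(a, b).score
        assert waterman_eggert(a, b, k_max=3, min_score=best + 1) == []

    def test_no_shared_residue_pairs_and_monotone_scores(self, rng):
        a, b = random_dna(150, rng), random_dna(150, rng)
        res = waterman_eggert(a, b, k_max=5, min_score=10)
        seen = set()
        for aln in res:
            i, j = aln.a_start, aln.b_start
            for ca, cb in zip(aln.a_gapped, aln.b_gapped):
                if ca != "-" and cb != "-":
                    assert (i, j) not in seen
                    seen.add((i, j))
                if ca != "-":
                    i += 1
                if cb != "-":
                    j += 1
        scores = [r.score for r in res]
        assert scores == sorted(scores, reverse=True)


class TestSplitAlignment:
    def test_bridged_blocks_split_into_two_hsps(self, rng):
        from crescan.align import split_alignment
        from crescan.synthetic import evolve_sequence

        c1, c2 = random_dna(150, rng), random_dna(150, rng)
        a = c1 + random_dna(200, rng) + c2
        b = (
            evolve_sequence(c1, 0.9, 0.05, 1)
            + random_dna(200, rng)
            + evolve_sequence(c2, 0.9, 0.05, 2)
        )
        merged = smith_waterman(a, b)
        pieces = split_alignment(merged)
        assert len(pieces) == 2
        assert all(p.identity > 0.8 for p in pieces)
        # pieces cover the two conserved blocks, not the spacer
        (p1, p2) = sorted(pieces, key=lambda p: p.a_start)
        assert p1.a_end <= 160 and p2.a_start >= 340

    def test_clean_alignment_returned_unchanged(self, rng):
        from crescan.align import split_alignment
        from crescan.synthetic import evolve_sequence

        a = random_dna(200, rng)
        b = evolve_sequence(a, 0.9, 0.0, 3)
        aln = smith_waterman(a, b)
        assert split_alignment(aln) == [aln]

    def test_piece_scores_reconstruct(self, rng):
        from crescan.align import ScoringScheme, split_alignment
        from crescan.synthetic import evolve_sequence

        sc = ScoringScheme()
        c1, c2 = random_dna(120, rng), random_dna(120, rng)
        a = c1 + random_dna(300, rng) + c2
        b = evolve_sequence(c1, 0.85, 0.05, 4) + random_dna(300, rng) + evolve_sequence(c2, 0.85, 0.05, 5)
        for piece in split_alignment(smith_waterman(a, b, sc), sc):
            assert piece.rescore(sc) == piece.score
            # intervals consistent with gapped strings
            assert piece.a_end - piece.a_start == sum(1 for ch in piece.a_gapped if ch != "-")


class TestAlignmentIdentity:
    @pytest.mark.parametrize(
        "ga,gb,expected",
        [
            ("ACGT", "ACGT", (4, 4, 1.0)),
            ("AC-GT", "ACCGT", (4, 5, 0.8)),
            ("ANGT", "AAGT", (3, 4, 0.75)),  # N never identical
        ],
    )
    def test_stated_conventions(self, ga, gb, expected):
        aln = LocalAlignment(0, 1, 0, 1, ga, gb, 0)
        assert alignment_identity(aln) == expected

    def test_unequal_lengths_error(self):
        aln = LocalAlignment(0, 1, 0, 1, "ACG", "AC", 0)
        with pytest.raises(ValueError, match="length"):
            alignment_identity(aln)
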