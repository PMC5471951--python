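"""ACS_k estimators: oracle, seed assignments, similarity and distance."""

import math

import numpy as np
import pytest

from acsphylo import (
    DistanceMatrix,
    InvalidInputError,
    SequenceRecord,
    acs_k,
    alpha_assignment,
    beta_assignment,
    beta_assignment_both,
    build_index,
    dist_k,
    exact_lambda_profile,
    lambda_profile,
    pairwise_matrices,
    pairwise_matrix,
)
from conftest import naive_lambda_profile, random_dna

WORKED_X = SequenceRecord("X", "ACGTACGT")
WORKED_Y = SequenceRecord("Y", "ACGAACGT")


class TestExactProfile:
    """The quadratic estimator is itself checked against pure-python scans."""

    def test_agrees_with_pure_python_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            x, y = random_dna(rng, 5, 40, "x"), random_dna(rng, 5, 40, "y")
            for k in range(4):
                prof = exact_lambda_profile(x, y, k)
                assert prof.lambdas.tolist() == naive_lambda_profile(
                    x.residues, y.residues, k
                )

    def test_worked_pair(self):
        assert exact_lambda_profile(WORKED_X, WORKED_Y, 1).lambdas[0] == 8

    def test_self_comparison_full_suffix_lengths(self):
        x = SequenceRecord("x", "GATTACA")
        for k in (0, 2):
            prof = exact_lambda_profile(x, x, k)
            assert prof.lambdas.tolist() == [7 - i for i in range(7)]

    def test_disjoint_alphabets_single_forgiven_mismatch(self):
        prof = exact_lambda_profile(
            SequenceRecord("x", "AAAA"), SequenceRecord("y", "CCCC"), 1
        )
        assert prof.lambdas.tolist() == [1, 1, 1, 1]

    def test_partners_are_smallest_maximizers(self):
        x, y = SequenceRecord("x", "TTT"), SequenceRecord("y", "GTGT")
        prof = exact_lambda_profile(x, y, 0)
        # "T" occurs at offsets 2 and 4; smallest wins
        assert prof.partners[2] == 2


class TestAlphaAssignment:
    def test_worked_pair_prefers_longer_exact_match(self):
        idx = build_index([WORKED_X, WORKED_Y])
        cand = alpha_assignment(idx, 0, 1)
        assert cand.a[0] == 5  # exact LCP 4 with Y_5 beats LCP 3 with Y_1
        assert cand.value[0] == 4

    def test_self_pair_full_lengths(self):
        x = SequenceRecord("x", "ACGTG")
        idx = build_index([x, SequenceRecord("y", x.residues)])
        cand = alpha_assignment(idx, 0, 1)
        assert cand.value.tolist() == [5, 4, 3, 2, 1]

    def test_disjoint_alphabets_tie_rule(self):
        idx = build_index([SequenceRecord("x", "AAA"), SequenceRecord("y", "CCC")])
        cand = alpha_assignment(idx, 0, 1)
        assert cand.value.tolist() == [0, 0, 0]
        assert cand.a.tolist() == [1, 1, 1]  # ties -> smallest offset

    def test_values_equal_exact_zero_mismatch_maxima(self, pair_corpus):
        for x, y in pair_corpus[:15]:
            idx = build_index([x, y])
            cand = alpha_assignment(idx, 0, 1)
            oracle = exact_lambda_profile(x, y, 0)
            assert cand.value.tolist() == oracle.lambdas.tolist()


class TestBetaAssignment:
    def test_worked_pair_beats_exact_seed(self):
        idx = build_index([WORKED_X, WORKED_Y])
        cand = beta_assignment(idx, 0, 1)
        assert cand.value[0] == 8
        assert cand.a[0] == 1

    def test_self_pair_full_lengths(self):
        x = SequenceRecord("x", "ACGTG")
        idx = build_index([x, SequenceRecord("y", x.residues)])
        assert beta_assignment(idx, 0, 1).value.tolist() == [5, 4, 3, 2, 1]

    def test_disjoint_alphabets(self):
        idx = build_index([SequenceRecord("x", "AAAA"), SequenceRecord("y", "CCCC")])
        assert beta_assignment(idx, 0, 1).value.tolist() == [1, 1, 1, 1]

    def test_equals_brute_force_one_mismatch_maximum(self, pair_corpus):
        """The greedy seed value is the exact 1-mismatch maximum everywhere."""
        for x, y in pair_corpus[:20]:
            idx = build_index([x, y])
            cand = beta_assignment(idx, 0, 1)
            oracle = exact_lambda_profile(x, y, 1)
            assert np.array_equal(cand.value, oracle.lambdas)

    def test_both_directions_consistent_with_single(self):
        rng = np.random.default_rng(37)
        x, y = random_dna(rng, 30, 80, "x"), random_dna(rng, 30, 80, "y")
        idx = build_index([x, y])
        both = beta_assignment_both(idx, 0, 1)
        assert np.array_equal(both[0].value, beta_assignment(idx, 0, 1).value)
        assert np.array_equal(both[1].value, beta_assignment(idx, 1, 0).value)


class TestLambdaProfile:
    def test_zero_mismatch_alpha_reduces_to_classic_acs(self, pair_corpus):
        x, y = pair_corpus[0]
        idx = build_index([x, y])
        prof = lambda_profile(idx, alpha_assignment(idx, 0, 1), 0)
        assert prof.lambdas.tolist() == exact_lambda_profile(x, y, 0).lambdas.tolist()

    def test_greedy_worked_pair(self):
        idx = build_index([WORKED_X, WORKED_Y])
        prof = lambda_profile(idx, beta_assignment(idx, 0, 1), 1)
        assert prof.lambdas[0] == 8
        assert prof.method == "greedy_1mm"

    def test_large_k_forgives_every_mismatch(self):
        from acsphylo import CandidateArray

        x = SequenceRecord("x", "ACACACAC")
        y = SequenceRecord("y", "AGAGAGAG")
        idx = build_index([x, y])
        # with partner 1 and budget >= the alternating mismatch count the
        # whole sequence matches
        seed = CandidateArray((0, 1), "greedy_1mm", np.ones(8, dtype=np.int64),
                              np.ones(8, dtype=np.int64))
        prof = lambda_profile(idx, seed, 8)
        assert prof.lambdas[0] == 8

    def test_mismatched_direction_is_usage_error(self):
        idx = build_index([WORKED_X, WORKED_Y])
        other = build_index([WORKED_X, SequenceRecord("Z", "AC")])
        seed = beta_assignment(idx, 0, 1)
        with pytest.raises(InvalidInputError):
            lambda_profile(other, seed, 1)

    def test_domination_and_k0_coincidence(self, pair_corpus):
        """lambda' <= lambda and lambda'' <= lambda for every position/k;
        all estimators coincide at k=0; greedy >= exact-seed at k=1."""
        for x, y in pair_corpus[:10]:
            idx = build_index([x, y])
            alpha = alpha_assignment(idx, 0, 1)
            beta = beta_assignment(idx, 0, 1)
            for k in range(4):
                lam = exact_lambda_profile(x, y, k).lambdas
                lam_p = lambda_profile(idx, alpha, k).lambdas
                lam_pp = lambda_profile(idx, beta, k).lambdas
                assert (lam_p <= lam).all()
                assert (lam_pp <= lam).all()
                if k == 0:
                    assert np.array_equal(lam_p, lam)
                    assert np.array_equal(lam_pp, lam)
                if k == 1:
                    assert (lam_pp >= lam_p).all()


class TestAcsAndDist:
    def test_self_comparison_closed_form(self):
        x = SequenceRecord("x", "ACGT")
        assert acs_k(exact_lambda_profile(x, x, 0)) == 2.5

    def test_forgiven_mismatch_average(self):
        prof = exact_lambda_profile(
            SequenceRecord("x", "AAAA"), SequenceRecord("y", "CCCC"), 1
        )
        assert acs_k(prof) == 1.0

    def test_dist_symmetry_exact(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            axy, ayx = rng.uniform(0.5, 20, 2)
            lx, ly = rng.integers(2, 10000, 2)
            assert dist_k(axy, ayx, lx, ly) == pytest.approx(
                dist_k(ayx, axy, ly, lx), abs=1e-12
            )

    def test_identical_length4_closed_form(self):
        expected = 2 * math.log(4) / 5 - 2 * math.log(4) / 4
        assert dist_k(2.5, 2.5, 4, 4) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.13863, abs=5e-6)

    def test_zero_similarity_is_infinite(self):
        assert dist_k(0.0, 2.0, 10, 10) == math.inf

    def test_short_sequences_rejected(self):
        with pytest.raises(InvalidInputError):
            dist_k(1.0, 1.0, 1, 4)

    def test_monotone_in_k(self):
        """ACS_k non-decreasing and Dist_k non-increasing in k."""
        rng = np.random.default_rng(43)
        for _ in range(5):
            x, y = random_dna(rng, 50, 150, "x"), random_dna(rng, 50, 150, "y")
            idx = build_index([x, y])
            bxy, byx = beta_assignment_both(idx, 0, 1)
            prev_acs, prev_dist = -1.0, math.inf
            for k in range(6):
                a_xy = acs_k(lambda_profile(idx, bxy, k))
                a_yx = acs_k(lambda_profile(idx, byx, k))
                d = dist_k(a_xy, a_yx, len(x), len(y))
                assert a_xy >= prev_acs - 1e-12
                assert d <= prev_dist + 1e-12
                prev_acs, prev_dist = a_xy, d


class TestPairwiseMatrix:
    def test_identical_pair_raw_and_clipped(self):
        seqs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]
        raw = pairwise_matrix(seqs, k=1, method="greedy")
        assert raw.d[0, 1] == pytest.approx(-0.138629, abs=1e-6)
        clipped = pairwise_matrix(seqs, k=1, method="greedy", clip_negative=True)
        assert clipped.d[0, 1] == 0.0

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(47)
        seqs = [random_dna(rng, 60, 120, f"s{i}") for i in range(5)]
        m = pairwise_matrix(seqs, k=1, method="greedy")
        assert np.array_equal(m.d, m.d.T)
        assert np.all(np.diag(m.d) == 0)

    def test_methods_coincide_at_k0(self):
        rng = np.random.default_rng(53)
        seqs = [random_dna(rng, 60, 120, f"s{i}") for i in range(3)]
        mats = pairwise_matrices(seqs, [("acs", 0), ("exact_seed", 0), ("greedy", 0)])
        d0 = mats[("acs", 0)].d
        assert np.array_equal(d0, mats[("exact_seed", 0)].d)
        assert np.array_equal(d0, mats[("greedy", 0)].d)

    def test_duplicate_names_rejected(self):
        seqs = [SequenceRecord("a", "ACGT"), SequenceRecord("a", "TTTT")]
        with pytest.raises(InvalidInputError):
            pairwise_matrix(seqs)

    def test_greedy_matches_exact_matrix_at_k1(self):
        rng = np.random.default_rng(59)
        seqs = [random_dna(rng, 40, 90, f"s{i}") for i in range(4)]
        mats = pairwise_matrices(seqs, [("greedy", 1), ("exact", 1)])
        assert np.allclose(mats[("greedy", 1)].d, mats[("exact", 1)].d, atol=1e-12)

    def test_unknown_method_rejected(self):
        seqs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "TTTT")]
        with pytest.raises(InvalidInputError):
            pairwise_matrix(seqs, method="banana")


class TestDistanceMatrixType:
    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidInputError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(InvalidInputError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))
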