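import math

import numpy as np
import pytest

from hmmball import (
    HMM,
    Labelling,
    ball_prob_border_shift,
    ball_prob_border_shift_sum,
    ball_prob_generalized_hamming,
    footprint_probability,
    forward,
    joint_probability,
    labelling_probability,
)
from hmmball.distances import BallSpec, LabelDistanceMatrix, footprint_of
from hmmball.oracle import brute_ball_probability, enumerate_labelling_probabilities


def nonzero_labellings(hmm, y, limit=None):
    labs = [(l, p) for l, p in enumerate_labelling_probabilities(hmm, y).items() if p > 0]
    labs.sort(key=lambda t: -t[1])
    return labs[:limit] if limit else labs


class TestLabellingProbability:
    def test_one_state_per_label_equals_joint_probability(self):
        hmm = HMM(
            transitions=np.array([[0.8, 0.2], [0.3, 0.7]]),
            emissions=np.array([[0.6, 0.4], [0.1, 0.9]]),
            alphabet=("a", "b"),
            start_state=0,
            labels=("A", "B"),
        )
        y, path = "abba", (0, 0, 1, 1, 0)
        lam = tuple(hmm.labels[s] for s in path)
        assert labelling_probability(hmm, y, lam) == pytest.approx(
            joint_probability(hmm, y, path), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_over_all_labellings(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=3, n=6)
        total = sum(labelling_probability(hmm, y, l) for l, _ in nonzero_labellings(hmm, y))
        assert total == pytest.approx(forward(hmm, y).probability, rel=1e-9)

    def test_unknown_label_in_footprint_gives_zero(self, make_random_instance):
        hmm, y = make_random_instance(0, m=2, n=4)
        lam = (hmm.start_label,) + ("Z",) * 4
        assert labelling_probability(hmm, y, lam) == 0.0

    def test_wrong_start_label_gives_zero(self, make_random_instance):
        hmm, y = make_random_instance(0, m=3, n=4)
        good, _ = nonzero_labellings(hmm, y, limit=1)[0]
        assert labelling_probability(hmm, y, ("not-the-start",) + good[1:]) == 0.0


class TestFootprintProbability:
    @pytest.mark.parametrize("seed", range(6))
    def test_equals_sum_over_matching_labellings(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=3, n=6)
        labs = nonzero_labellings(hmm, y)
        fps = {footprint_of(l) for l, _ in labs}
        for f in fps:
            expect = sum(p for l, p in labs if footprint_of(l) == f)
            assert footprint_probability(hmm, y, f) == pytest.approx(expect, rel=1e-9)

    def test_single_label_footprint_restricts_to_label_class(self):
        hmm = HMM(
            transitions=np.array([[0.5, 0.5], [0.5, 0.5]]),
            emissions=np.array([[0.7, 0.3], [0.2, 0.8]]),
            alphabet=("a", "b"),
            start_state=0,
            labels=("A", "A"),
        )
        assert footprint_probability(hmm, "ab", ("A",)) == pytest.approx(
            forward(hmm, "ab").probability, rel=1e-12
        )

    def test_footprint_longer_than_sequence_impossible(self, make_random_instance):
        hmm, y = make_random_instance(1, m=3, n=3)
        f = ("A", "B") * 3
        assert footprint_probability(hmm, y, f[: len(y) + 1]) == 0.0

    def test_repeated_consecutive_labels_rejected(self, make_random_instance):
        hmm, y = make_random_instance(1)
        with pytest.raises(ValueError, match="consecutive"):
            footprint_probability(hmm, y, ("A", "A"))


class TestBallProbabilities:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("r", [0, 1, 2])
    def test_border_shift_matches_enumeration(self, make_random_instance, seed, r):
        hmm, y = make_random_instance(seed, m=3, n=6)
        for lam, _ in nonzero_labellings(hmm, y, limit=3):
            spec = BallSpec(Labelling(lam), r, "border_shift")
            assert ball_prob_border_shift(hmm, y, lam, r) == pytest.approx(
                brute_ball_probability(hmm, y, spec), rel=1e-9
            )

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("r", [0, 1, 3])
    def test_border_shift_sum_matches_enumeration(self, make_random_instance, seed, r):
        hmm, y = make_random_instance(seed, m=3, n=6)
        for lam, _ in nonzero_labellings(hmm, y, limit=3):
            spec = BallSpec(Labelling(lam), r, "border_shift_sum")
            assert ball_prob_border_shift_sum(hmm, y, lam, r) == pytest.approx(
                brute_ball_probability(hmm, y, spec), rel=1e-9
            )

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("r", [0, 1, 2])
    def test_generalized_hamming_matches_enumeration(self, make_random_instance, seed, r):
        hmm, y = make_random_instance(seed, m=3, n=6)
        H = LabelDistanceMatrix.hamming(hmm.label_set)
        for lam, _ in nonzero_labellings(hmm, y, limit=3):
            spec = BallSpec(Labelling(lam), r, "generalized_hamming", H)
            assert ball_prob_generalized_hamming(hmm, y, lam, r, H) == pytest.approx(
                brute_ball_probability(hmm, y, spec), rel=1e-9
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_limit_identities(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=3, n=6)
        n = len(y)
        H0 = LabelDistanceMatrix.zero(hmm.label_set)
        H1 = LabelDistanceMatrix.hamming(hmm.label_set)
        py = forward(hmm, y).probability
        for lam, _ in nonzero_labellings(hmm, y, limit=3):
            lp = labelling_probability(hmm, y, lam)
            # radius 0 collapses every metric to the bare labelling
            assert ball_prob_border_shift(hmm, y, lam, 0) == pytest.approx(lp, rel=1e-12)
            assert ball_prob_border_shift_sum(hmm, y, lam, 0) == pytest.approx(lp, rel=1e-12)
            # radius n frees the borders entirely
            assert ball_prob_border_shift(hmm, y, lam, n) == pytest.approx(
                footprint_probability(hmm, y, footprint_of(lam)), rel=1e-12
            )
            # a zero penalty matrix puts every labelling at distance 0
            assert ball_prob_generalized_hamming(hmm, y, lam, 0, H0) == pytest.approx(
                py, rel=1e-12
            )
            assert ball_prob_generalized_hamming(hmm, y, lam, n, H1) == pytest.approx(
                py, rel=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_radius_and_nested(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=3, n=6)
        H = LabelDistanceMatrix.hamming(hmm.label_set)
        py = forward(hmm, y).probability
        tol = 1 + 1e-12
        for lam, _ in nonzero_labellings(hmm, y, limit=3):
            lp = labelling_probability(hmm, y, lam)
            fp = footprint_probability(hmm, y, footprint_of(lam))
            prev = {"shift": 0.0, "sum": 0.0, "ham": 0.0}
            for r in range(0, 4):
                bs = ball_prob_border_shift(hmm, y, lam, r)
                bss = ball_prob_border_shift_sum(hmm, y, lam, r)
                bh = ball_prob_generalized_hamming(hmm, y, lam, r, H)
                assert bs >= prev["shift"] / tol
                assert bss >= prev["sum"] / tol
                assert bh >= prev["ham"] / tol
                prev = {"shift": bs, "sum": bss, "ham": bh}
                assert bss <= bs * tol  # shift-sum ball is a subset
                assert lp <= bs * tol <= fp * tol * tol <= py * tol**3

    def test_infeasible_centre_footprint_gives_zero(self, make_random_instance):
        hmm, y = make_random_instance(2, m=2, n=4)
        lam = (hmm.start_label,) + ("Z",) * len(y)
        assert ball_prob_border_shift(hmm, y, lam, 2) == 0.0
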