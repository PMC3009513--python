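import math

import numpy as np
import pytest

from hmmball import (
    HMM,
    StatePath,
    backward,
    forward,
    joint_probability,
    posterior_state_probs,
    sample_path_posterior,
    viterbi,
)
from hmmball.hmm_core import log_dot_identity
from hmmball.oracle import enumerate_path_probabilities


class TestJointProbability:
    def test_deterministic_emitter_gives_one(self, one_state_emitter):
        assert joint_probability(one_state_emitter, "aaa", (0, 0, 0, 0)) == 1.0

    def test_forbidden_transition_gives_zero(self, two_state_hmm):
        hmm = two_state_hmm
        blocked = HMM(
            transitions=np.array([[1.0, 0.0], [0.4, 0.6]]),
            emissions=hmm.emissions,
            alphabet=hmm.alphabet,
            start_state=0,
            labels=hmm.labels,
        )
        assert joint_probability(blocked, "ab", (0, 0, 1)) == 0.0

    def test_matches_term_by_term_hand_expansion(self, two_state_hmm):
        # independent oracle: multiply the a*e factors out explicitly
        hmm = two_state_hmm
        path, y = (0, 0, 1, 1), "aba"
        expected = 1.0
        for i in range(1, 4):
            expected *= hmm.transitions[path[i - 1], path[i]]
            expected *= hmm.emissions[path[i], hmm.symbol_index[y[i - 1]]]
        assert joint_probability(hmm, y, path) == pytest.approx(expected, rel=1e-15)

    def test_length_mismatch_rejected(self, two_state_hmm):
        with pytest.raises(ValueError, match="length"):
            joint_probability(two_state_hmm, "ab", (0, 1))


class TestForwardBackward:
    @pytest.mark.parametrize("seed", range(6))
    def test_forward_equals_exhaustive_path_sum(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=2, n=6)
        total = sum(p for _, p in enumerate_path_probabilities(hmm, y))
        assert forward(hmm, y).probability == pytest.approx(total, rel=1e-9)

    def test_deterministic_emitter_probability_one(self, one_state_emitter):
        assert forward(one_state_emitter, "aaaa").probability == 1.0

    def test_unemittable_symbol_gives_zero(self, one_state_emitter):
        ft = forward(one_state_emitter, "ab")
        assert ft.probability == 0.0
        assert ft.log_probability == -math.inf

    def test_unknown_symbol_rejected(self, one_state_emitter):
        with pytest.raises(ValueError, match="alphabet"):
            forward(one_state_emitter, "ax")

    @pytest.mark.parametrize("seed", range(4))
    def test_dot_product_identity_all_positions(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=3, n=8)
        ft, bt = forward(hmm, y), backward(hmm, y)
        for i in (0, len(y) // 2, len(y)):
            assert log_dot_identity(ft, bt, i) == pytest.approx(
                ft.log_probability, rel=1e-9, abs=1e-9
            )

    def test_one_state_emitter_backward_is_one(self, one_state_emitter):
        bt = backward(one_state_emitter, "aaa")
        for i in range(1, 5):
            assert bt.scaled[i, 0] * math.exp(bt.cum_log[i]) == pytest.approx(1.0)

    def test_unreachable_state_gets_no_forward_mass(self):
        hmm = HMM(
            transitions=np.array([[1.0, 0.0], [0.5, 0.5]]),
            emissions=np.array([[0.5, 0.5], [0.5, 0.5]]),
            alphabet=("a", "b"),
            start_state=0,
            labels=("A", "B"),
        )
        ft = forward(hmm, "abab")
        assert np.all(ft.scaled[1:, 1] == 0.0)
        bt = backward(hmm, "abab")  # beta still defined at the unreachable state
        assert np.all(np.isfinite(bt.cum_log[1:]))


class TestViterbi:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_argmax(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=3, n=6)
        paths = enumerate_path_probabilities(hmm, y)
        best = max(p for _, p in paths)
        path, prob = viterbi(hmm, y)
        assert prob == pytest.approx(best, rel=1e-9)
        assert joint_probability(hmm, y, path) == pytest.approx(prob, rel=1e-9)

    def test_deterministic_chain(self):
        hmm = HMM(
            transitions=np.array([[0.0, 1.0], [1.0, 0.0]]),
            emissions=np.array([[1.0, 0.0], [0.0, 1.0]]),
            alphabet=("a", "b"),
            start_state=0,
            labels=("A", "B"),
        )
        path, prob = viterbi(hmm, "bab")
        assert tuple(path) == (0, 1, 0, 1)
        assert prob == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_never_exceeds_forward_total(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=4, n=7)
        _, prob = viterbi(hmm, y)
        assert prob <= forward(hmm, y).probability * (1 + 1e-12)


class TestPosterior:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_marginals(self, make_random_instance, seed):
        hmm, y = make_random_instance(seed, m=3, n=5)
        paths = enumerate_path_probabilities(hmm, y)
        total = sum(p for _, p in paths)
        gamma = posterior_state_probs(hmm, y)
        assert np.allclose(gamma.sum(axis=1), 1.0)
        for i in range(1, len(y) + 1):
            for k in range(hmm.m):
                marg = sum(p for path, p in paths if path[i] == k) / total
                assert gamma[i - 1, k] == pytest.approx(marg, rel=1e-9, abs=1e-12)

    def test_single_state_model_concentrates(self, one_state_emitter):
        gamma = posterior_state_probs(one_state_emitter, "aa")
        assert np.all(gamma == 1.0)


class TestPosteriorSampling:
    def test_unique_feasible_path_always_returned(self):
        hmm = HMM(
            transitions=np.array([[0.0, 1.0], [1.0, 0.0]]),
            emissions=np.array([[1.0, 0.0], [0.0, 1.0]]),
            alphabet=("a", "b"),
            start_state=0,
            labels=("A", "B"),
        )
        for seed in range(5):
            assert tuple(sample_path_posterior(hmm, "bab", seed)) == (0, 1, 0, 1)

    def test_same_seed_reproduces_path(self, make_random_instance):
        hmm, y = make_random_instance(3, m=3, n=8)
        assert tuple(sample_path_posterior(hmm, y, 11)) == tuple(
            sample_path_posterior(hmm, y, 11)
        )

    def test_zero_probability_sequence_rejected(self, one_state_emitter):
        with pytest.raises(ValueError, match="Pr\\[y\\]"):
            sample_path_posterior(one_state_emitter, "ab", 0)

    def test_empirical_frequencies_track_conditionals(self, make_random_instance):
        # small-n calibration check; the full 50k-draw version lives in the
        # acceptance suite
        hmm, y = make_random_instance(0, m=2, n=3)
        paths = enumerate_path_probabilities(hmm, y)
        total = sum(p for _, p in paths)
        cond = {path: p / total for path, p in paths}
        rng = np.random.default_rng(5)
        draws = 4000
        counts: dict = {}
        for _ in range(draws):
            t = tuple(sample_path_posterior(hmm, y, rng))
            counts[t] = counts.get(t, 0) + 1
        for path, q in cond.items():
            se = math.sqrt(q * (1 - q) / draws)
            assert abs(counts.get(path, 0) / draws - q) <= max(4 * se, 5 / draws)
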