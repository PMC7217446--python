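"""Softmax and linear-chain CRF heads against exhaustive-enumeration oracles."""

import itertools

import numpy as np
import pytest

from caseseq.autodiff import Tensor
from caseseq.heads import (
    CrfHead,
    SoftmaxHead,
    crf_log_likelihood,
    crf_log_partition,
    crf_sequence_score,
    transition_diagnostic,
    viterbi_decode,
)


def enumerate_log_partition(emissions, transitions):
    """Brute-force logZ: sum of exp(score) over all K^n label paths."""
    n, k = emissions.shape
    scores = [
        crf_sequence_score(emissions, transitions, np.array(path))
        for path in itertools.product(range(k), repeat=n)
    ]
    m = max(scores)
    return m + np.log(np.sum(np.exp(np.array(scores) - m)))


def enumerate_best_path(emissions, transitions):
    n, k = emissions.shape
    best, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=n):
        s = crf_sequence_score(emissions, transitions, np.array(path))
        if s > best_score + 1e-12:
            best, best_score = np.array(path), s
    return best, best_score


class TestSoftmaxHead:
    def test_zero_logits_give_uniform(self):
        head = SoftmaxHead(4, 5, seed=0)
        head.W.data[...] = 0.0
        probs = head.predict_proba(np.ones((3, 4)))
        assert np.allclose(probs, 0.2)

    def test_two_class_logistic_value(self):
        head = SoftmaxHead(2, 2, seed=0)
        head.W.data = np.eye(2)
        head.b.data[...] = 0.0
        probs = head.predict_proba(np.array([[1.0, 0.0]]))
        assert probs[0] == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_distributions_sum_to_one(self, rng):
        head = SoftmaxHead(6, 7, seed=1)
        probs = head.predict_proba(rng.normal(size=(10, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestCrfOracle:
    def test_length_one_sequence_is_plain_softmax(self, rng):
        emissions = rng.normal(size=(1, 3))
        t = rng.normal(size=(3, 3))
        logz = crf_log_partition(emissions, t)
        from scipy.special import logsumexp

        assert logz == pytest.approx(logsumexp(emissions[0]), abs=1e-12)
        ll = crf_log_likelihood(emissions, t, np.array([2]))
        assert ll == pytest.approx(emissions[0, 2] - logz, abs=1e-12)

    def test_forward_logz_matches_enumeration_100_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(1, 6))
            emissions = rng.normal(size=(n, k)) * 2
            transitions = rng.normal(size=(k, k)) * 2
            assert crf_log_partition(emissions, transitions) == pytest.approx(
                enumerate_log_partition(emissions, transitions), abs=1e-6
            )

    def test_viterbi_matches_enumeration_100_instances(self):
        rng = np.random.default_rng(88)
        for _ in range(100):
            k = int(rng.integers(2, 4))
            n = int(rng.integers(1, 6))
            emissions = rng.normal(size=(n, k)) * 2
            transitions = rng.normal(size=(k, k)) * 2
            path = viterbi_decode(emissions, transitions)
            best, best_score = enumerate_best_path(emissions, transitions)
            assert crf_sequence_score(emissions, transitions, path) == pytest.approx(
                best_score, abs=1e-9
            )
            assert np.array_equal(path, best)

    def test_zero_transitions_decompose_into_per_position_softmax(self, rng):
        emissions = rng.normal(size=(4, 3))
        zeros = np.zeros((3, 3))
        labels = np.array([0, 2, 1, 1])
        from scipy.special import logsumexp

        per_position = sum(
            emissions[i, labels[i]] - logsumexp(emissions[i]) for i in range(4)
        )
        assert crf_log_likelihood(emissions, zeros, labels) == pytest.approx(
            per_position, abs=1e-10
        )
        assert np.array_equal(
            viterbi_decode(emissions, zeros), emissions.argmax(axis=1)
        )

    def test_strong_diagonal_transitions_enforce_constant_path(self):
        # one emission disagrees, but off-diagonal transitions are ruinous
        emissions = np.array([[5.0, 0.0], [0.0, 1.0], [5.0, 0.0]])
        transitions = np.array([[0.0, -50.0], [-50.0, 0.0]])
        path = viterbi_decode(emissions, transitions)
        assert np.array_equal(path, [0, 0, 0])
        best, _ = enumerate_best_path(emissions, transitions)
        assert np.array_equal(best, path)

    def test_logz_upper_bounds_every_path_score(self, rng):
        emissions = rng.normal(size=(3, 3))
        transitions = rng.normal(size=(3, 3))
        logz = crf_log_partition(emissions, transitions)
        for path in itertools.product(range(3), repeat=3):
            assert logz > crf_sequence_score(emissions, transitions, np.array(path))

    def test_viterbi_tie_breaks_to_lowest_class(self):
        emissions = np.zeros((3, 3))
        transitions = np.zeros((3, 3))
        assert np.array_equal(viterbi_decode(emissions, transitions), [0, 0, 0])


class TestCrfHead:
    def test_head_loglik_matches_functional_form(self, rng):
        head = CrfHead(5, 3, seed=2)
        head.transitions.data = rng.normal(size=(3, 3))
        outputs = rng.normal(size=(4, 5))
        labels = np.array([1, 0, 2, 2])
        emissions = outputs @ head.W.data + head.b.data
        expected = crf_log_likelihood(emissions, head.transitions.data, labels)
        got = head.log_likelihood(Tensor(outputs), labels)
        assert got.item() == pytest.approx(expected, abs=1e-10)

    def test_label_outside_class_set_rejected(self, rng):
        head = CrfHead(4, 3, seed=0)
        with pytest.raises(ValueError, match="class set"):
            head.log_likelihood(Tensor(rng.normal(size=(2, 4))), np.array([0, 3]))

    def test_gradient_of_loglik_flows_to_transitions(self, rng):
        head = CrfHead(4, 3, seed=1)
        loss = -head.log_likelihood(
            Tensor(rng.normal(size=(3, 4))), np.array([0, 0, 0])
        )
        loss.backward()
        assert head.transitions.grad is not None
        assert np.abs(head.transitions.grad).sum() > 0


def test_transition_diagnostic_sign():
    assert transition_diagnostic(np.eye(3)) > 0
    assert transition_diagnostic(1 - np.eye(3)) < 0
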