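"""Voting rules against brute-force oracles; stacking contracts."""

import itertools

import numpy as np
import pytest

from masscontext.datatypes import Label
from masscontext.fusion import (
    fit_stacker,
    majority_vote,
    make_stacker,
    max_vote,
    predict_stacked,
    soft_vote,
    vote,
)


def _brute_majority(labels):
    counts = {0: 0, 1: 0}
    for l in labels:
        counts[int(l)] += 1
    if counts[0] > counts[1]:
        return Label.BENIGN
    return Label.MALIGNANT  # ties to the positive class


class TestMajorityVote:
    def test_simple_majorities(self):
        assert majority_vote([0, 0, 1]) == Label.BENIGN
        assert majority_vote([1] * 11) == Label.MALIGNANT
        assert majority_vote([0] * 11) == Label.BENIGN

    def test_exhaustive_agreement_with_oracle(self):
        for n in range(1, 8):
            for labels in itertools.product([0, 1], repeat=n):
                assert majority_vote(labels) == _brute_majority(labels), labels

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


GRID = [0.0, 0.25, 0.5, 0.75, 1.0]


def _prob_sequences(max_len=3):
    for n in range(1, max_len + 1):
        for p1s in itertools.product(GRID, repeat=n):
            yield [(p1, 1 - p1) for p1 in p1s]


class TestSoftVote:
    def test_arithmetic_example(self):
        label, mean = soft_vote([(0.6, 0.4), (0.2, 0.8)])
        np.testing.assert_allclose(mean, [0.4, 0.6])
        assert label == Label.MALIGNANT

    def test_single_pair_is_argmax(self):
        assert soft_vote([(0.9, 0.1)])[0] == Label.BENIGN

    def test_exact_tie_goes_malignant(self):
        assert soft_vote([(0.5, 0.5), (0.5, 0.5)])[0] == Label.MALIGNANT

    def test_exhaustive_agreement_with_mean_oracle(self):
        for probs in _prob_sequences():
            label, mean = soft_vote(probs)
            arr = np.asarray(probs)
            np.testing.assert_allclose(mean, arr.mean(axis=0))
            expected = Label.BENIGN if mean[0] > mean[1] else Label.MALIGNANT
            assert label == expected


class TestMaxVote:
    def test_arithmetic_example(self):
        label, mx = max_vote([(0.6, 0.4), (0.2, 0.8)])
        np.testing.assert_allclose(mx, [0.6, 0.8])
        assert label == Label.MALIGNANT

    def test_uniform_ties_go_malignant(self):
        assert max_vote([(0.5, 0.5)] * 5)[0] == Label.MALIGNANT

    def test_exhaustive_agreement_with_max_oracle(self):
        for probs in _prob_sequences():
            label, mx = max_vote(probs)
            arr = np.asarray(probs)
            np.testing.assert_allclose(mx, arr.max(axis=0))
            expected = Label.BENIGN if mx[0] > mx[1] else Label.MALIGNANT
            assert label == expected


class TestVotingProperties:
    def test_permutation_invariance(self, rng):
        p1 = rng.uniform(0, 1, 7)
        probs = np.column_stack([p1, 1 - p1])
        for rule in ("majority", "soft", "max"):
            base = vote(rule, probs)
            for _ in range(5):
                perm = rng.permutation(7)
                assert vote(rule, probs[perm]) == base

    def test_empty_rejected(self):
        for rule in ("majority", "soft", "max"):
            with pytest.raises(ValueError):
                vote(rule, np.empty((0, 2)))


def _toy_vectors(n=50, length=11, seed=0):
    """Separable stack vectors: benign mean 0.2, malignant mean 0.8."""
    rng = np.random.default_rng(seed)
    x0 = np.clip(rng.normal(0.2, 0.08, (n, length)), 0, 1)
    x1 = np.clip(rng.normal(0.8, 0.08, (n, length)), 0, 1)
    x = np.vstack([x0, x1])
    y = np.array([0] * n + [1] * n)
    return x, y


class TestStacking:
    @pytest.mark.parametrize(
        "kind", ["svm_rbf", "svm_linear", "svm_poly", "random_forest"]
    )
    def test_separable_training_is_perfect(self, kind):
        x, y = _toy_vectors()
        model = fit_stacker(x, y, kind=kind)
        assert (predict_stacked(model, x) == y).all()

    def test_all_zero_vector_is_benign(self):
        x, y = _toy_vectors()
        model = fit_stacker(x, y)
        assert predict_stacked(model, np.zeros(11)) == 0

    def test_prediction_is_deterministic(self):
        x, y = _toy_vectors()
        model = fit_stacker(x, y)
        v = np.full(11, 0.45)
        assert predict_stacked(model, v) == predict_stacked(model, v)

    def test_length_mismatch_rejected(self):
        x, y = _toy_vectors()
        model = fit_stacker(x, y)
        with pytest.raises(ValueError):
            predict_stacked(model, np.zeros(7))

    def test_single_class_rejected(self):
        x, _ = _toy_vectors()
        with pytest.raises(ValueError):
            fit_stacker(x, np.zeros(x.shape[0], dtype=int))

    def test_order_sensitivity(self):
        """Stack vectors are positional: permuting ROI order changes the
        decision function (unlike the voting rules)."""
        rng = np.random.default_rng(1)
        n = 60
        # class depends on the FIRST coordinate only
        x = rng.uniform(0, 1, (n, 11))
        y = (x[:, 0] > 0.5).astype(int)
        model = fit_stacker(x, y, kind="svm_linear")
        probe = np.r_[0.95, np.full(10, 0.05)]
        rolled = np.roll(probe, 1)
        assert predict_stacked(model, probe) == 1
        assert predict_stacked(model, rolled) == 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_stacker("svm_sigmoid")
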