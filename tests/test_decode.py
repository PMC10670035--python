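"""LDA/SVM decoding, ROC thresholding, cross-validation, and ITR."""

import dataclasses
import warnings

import numpy as np
import pytest

from rsvpweak.channels import ChannelSubset
from rsvpweak.decode import (
    balanced_accuracy,
    cross_validate,
    itr,
    train_lda,
    train_svm,
    youden_threshold,
)
from rsvpweak.preprocess import EpochSet


def _gaussian_classes(rng, n=100, d=4, sep=4.0):
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.arange(2 * n) >= n
    return X, y


def _brute_force_youden(scores, labels):
    order = np.sort(np.unique(scores))
    cuts = np.concatenate([[order[0] - 1],
                           (order[:-1] + order[1:]) / 2.0,
                           [order[-1] + 1]])
    best = -np.inf
    for c in cuts:
        pred = scores > c
        sens = pred[labels].mean()
        spec = (~pred[~labels]).mean()
        best = max(best, sens + spec - 1)
    return best


class TestLda:
    def test_separable_classes_train_perfectly(self, rng):
        X, y = _gaussian_classes(rng, sep=6.0)
        model = train_lda(X, y)
        assert (model.predict(X) == y).all()

    def test_threshold_achieves_brute_force_youden_optimum(self, rng):
        for _ in range(20):
            X, y = _gaussian_classes(rng, n=40, sep=rng.uniform(0.5, 3.0))
            model = train_lda(X, y)
            scores = model.scores(X)
            pred = scores > model.xi
            j = pred[y].mean() + (~pred[~y]).mean() - 1
            assert j == pytest.approx(_brute_force_youden(scores, y), abs=1e-12)

    def test_swapping_classes_flips_decisions(self, rng):
        X, y = _gaussian_classes(rng, sep=5.0)
        flipped = train_lda(X, ~y)
        original = train_lda(X, y)
        test = rng.normal(2.0, 1.0, (50, 4))
        assert np.array_equal(original.predict(test), ~flipped.predict(test))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            train_lda(X, np.ones(10, bool))

    def test_identical_class_means_rejected(self):
        X = np.zeros((10, 3))
        y = np.arange(10) < 5
        with pytest.raises(ValueError):
            train_lda(X, y, reg=1.0)

    def test_diagonal_loading_mode(self, rng):
        X, y = _gaussian_classes(rng, sep=5.0)
        model = train_lda(X, y, reg=1e-3)
        assert (model.predict(X) == y).mean() > 0.99


class TestSvm:
    def test_xor_pattern_separable_with_rbf(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]] * 10, dtype=float)
        X += np.random.default_rng(0).normal(0, 0.05, X.shape)
        y = np.array([False, False, True, True] * 10)
        model = train_svm(X, y, g=2.0, cost=10.0)
        assert (model.predict(X) == y).all()

    def test_decision_function_matches_explicit_kernel_sum(self, rng):
        X, y = _gaussian_classes(rng, n=30, sep=2.0)
        model = train_svm(X, y, g=0.3, cost=1.0)
        probe = rng.normal(0.5, 1.5, (20, 4))
        direct = np.array([
            sum(w * np.exp(-model.kernel_width * np.sum((sv - x) ** 2))
                for w, sv in zip(model.weights, model.support_vectors))
            + model.bias
            for x in probe
        ])
        np.testing.assert_allclose(model.decision_function(probe), direct,
                                   rtol=1e-10)
        # and agrees with the fitted backend on its own support vectors
        np.testing.assert_allclose(
            model.decision_function(model.support_vectors),
            model._clf.decision_function(model.support_vectors), rtol=1e-8)

    def test_deterministic(self, rng):
        X, y = _gaussian_classes(rng, n=50, sep=1.0)
        a = train_svm(X, y, g=0.5)
        b = train_svm(X, y, g=0.5)
        probe = rng.normal(size=(10, 4))
        np.testing.assert_array_equal(a.predict(probe), b.predict(probe))

    @pytest.mark.parametrize("g,cost", [(-1.0, 1.0), (0.0, 1.0), (1.0, 0.0)])
    def test_invalid_hyperparameters(self, g, cost, rng):
        X, y = _gaussian_classes(rng, n=10)
        with pytest.raises(ValueError):
            train_svm(X, y, g=g, cost=cost)


def test_balanced_accuracy_is_mean_of_sensitivity_and_specificity():
    y = np.array([True] * 4 + [False] * 8)
    pred = np.array([True, True, True, False] + [False] * 6 + [True] * 2)
    # sens 3/4, spec 6/8
    assert balanced_accuracy(y, pred) == pytest.approx(75.0)


def _epochs_from_arrays(data, labels):
    n, nch = data.shape[:2]
    return EpochSet(data=data, labels=np.asarray(labels, bool),
                    condition=np.array(["C1"] * n, dtype=object), rate=125.0,
                    channels=tuple(f"CH{i}" for i in range(nch)))


class TestCrossValidate:
    def test_pure_noise_decodes_at_chance(self, rng):
        data = rng.normal(size=(300, 3, 20))
        labels = rng.permutation(np.arange(300) < 30)
        ep = _epochs_from_arrays(data, labels)
        res = cross_validate(ep, classifier="lda", seed=1)
        assert abs(res.mean - 50.0) <= max(3 * res.stderr, 2.0)

    def test_perfectly_distinct_classes_decode_fully(self):
        data = np.zeros((120, 2, 10))
        labels = np.arange(120) < 60
        data[labels] += 5.0
        data += np.random.default_rng(0).normal(0, 0.01, data.shape)
        ep = _epochs_from_arrays(data, labels)
        res = cross_validate(ep, classifier="lda", seed=0, reps=2)
        assert res.mean == pytest.approx(100.0)

    def test_deterministic_given_seed(self, rng):
        data = rng.normal(size=(240, 2, 15))
        labels = np.arange(240) < 40
        data[labels, 0, 5:10] += 0.8
        ep = _epochs_from_arrays(data, labels)
        a = cross_validate(ep, classifier="lda", seed=9, reps=2)
        b = cross_validate(ep, classifier="lda", seed=9, reps=2)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_channel_subset_restriction(self, rng):
        data = rng.normal(size=(240, 3, 15))
        labels = np.arange(240) < 40
        data[labels, 2, 5:10] += 1.5  # signal only in CH2
        ep = _epochs_from_arrays(data, labels)
        good = cross_validate(ep, ChannelSubset("s", ("CH2",)), seed=1, reps=3)
        bad = cross_validate(ep, ChannelSubset("n", ("CH0",)), seed=1, reps=3)
        assert good.mean > bad.mean + 10

    def test_too_few_epochs_per_class_rejected(self, rng):
        ep = _epochs_from_arrays(rng.normal(size=(20, 2, 10)),
                                 np.arange(20) < 3)
        with pytest.raises(ValueError):
            cross_validate(ep, folds=6)

    def test_result_summaries(self, rng):
        data = rng.normal(size=(120, 2, 10))
        ep = _epochs_from_arrays(data, np.arange(120) < 60)
        res = cross_validate(ep, classifier="lda", seed=0, reps=2)
        assert res.accuracies.shape == (2, 6)
        assert 0 <= res.mean <= 100 and res.stderr >= 0


class TestItr:
    def test_chance_level_two_commands_is_zero(self):
        assert itr(0.5, N=2, T=1.0) == pytest.approx(0.0)

    def test_perfect_ten_command_minutely_rate(self):
        assert itr(1.0, N=10, T=60.0) == pytest.approx(np.log2(10))

    def test_matches_direct_formula_on_grid(self):
        for P in (0.2, 0.5, 0.7965, 0.95, 1.0):
            for N in (2, 6, 10):
                for T in (0.5, 2.0, 60.0):
                    if P < 1.0 / N:
                        continue
                    bits = np.log2(N) + P * np.log2(P)
                    if P < 1:
                        bits += (1 - P) * np.log2((1 - P) / (N - 1))
                    assert itr(P, N, T) == pytest.approx(60.0 / T * bits)

    def test_monotone_in_accuracy_and_inverse_in_period(self):
        grid = np.linspace(0.1, 1.0, 40)
        vals = [itr(p, N=10, T=2.0) for p in grid]
        assert np.all(np.diff(vals) >= -1e-12)
        assert itr(0.8, N=10, T=1.0) == pytest.approx(2 * itr(0.8, N=10, T=2.0))

    def test_below_chance_warns_and_clamps(self):
        with pytest.warns(UserWarning):
            assert itr(0.05, N=10, T=2.0) == 0.0
        with pytest.warns(UserWarning):
            raw = itr(0.05, N=10, T=2.0, clamp=False)
        # the raw expression is >= 0 even below chance (minimum at P = 1/N)
        bits = np.log2(10) + 0.05 * np.log2(0.05) + 0.95 * np.log2(0.95 / 9)
        assert raw == pytest.approx(30.0 * bits)
        assert raw >= 0.0

    @pytest.mark.parametrize("kwargs", [
        {"P": 0.0}, {"P": 1.2}, {"P": 0.5, "N": 1}, {"P": 0.5, "T": 0.0},
    ])
    def test_domain_errors(self, kwargs):
        args = {"P": 0.5, "N": 2, "T": 1.0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            itr(**args)
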