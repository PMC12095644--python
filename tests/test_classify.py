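"""Gaussian naive Bayes training, posteriors, and whole-image prediction."""

import math

import numpy as np
import pytest

from flowseg.classify import (
    PixelClassifierModel,
    predict_mask,
    train_classifier,
)
from flowseg.exceptions import TrainingError
from flowseg.features import FeatureTable
from flowseg.io import IntensityImage
from flowseg.self_label import BACKGROUND, CELL


def make_table(values, labels):
    values = np.asarray(values, dtype=float)
    coords = np.column_stack([np.arange(len(values)), np.zeros(len(values), int)])
    return FeatureTable(coords=coords, values=values, labels=np.asarray(labels, np.uint8))


def bruteforce_log_posteriors(priors, means, variances, x):
    """Independent scalar-loop Bayes: log prior + summed log Gaussians, normalized."""
    out = []
    for row in x:
        joint = []
        for c in range(2):
            lp = math.log(priors[c]) if priors[c] > 0 else -math.inf
            for j in range(3):
                var = variances[c][j]
                lp += -0.5 * math.log(2 * math.pi * var)
                lp += -0.5 * (row[j] - means[c][j]) ** 2 / var
            joint.append(lp)
        mx = max(joint)
        lse = mx + math.log(sum(math.exp(v - mx) for v in joint))
        out.append([v - lse for v in joint])
    return np.array(out)


class TestTraining:
    def test_separable_classes_give_perfect_folds(self, rng):
        n = 60
        e = np.r_[np.zeros(n), np.full(n, 5.0)] + rng.normal(0, 0.01, 2 * n)
        g = np.full(2 * n, 0.3)
        i = np.full(2 * n, 0.5)
        labels = np.r_[np.full(n, BACKGROUND), np.full(n, CELL)]
        model = train_classifier(make_table(np.c_[e, g, i], labels), folds=10, seed=0)
        assert model.cv_accuracies == tuple([1.0] * 10)
        assert model.cv_mean == 1.0

    def test_indistinguishable_classes_give_chance_accuracy(self, rng):
        # under the null (identical class distributions) accuracy ~ 0.5
        n = 2000
        x = rng.normal(0.0, 1.0, (2 * n, 3))
        labels = np.r_[np.full(n, BACKGROUND), np.full(n, CELL)]
        model = train_classifier(make_table(x, labels), folds=10, seed=0)
        # 3 sigma of a binomial mean at n_total samples
        assert abs(model.cv_mean - 0.5) < 3 * math.sqrt(0.25 / (2 * n))

    def test_too_few_rows_per_class_fails(self, rng):
        x = rng.random((12, 3))
        labels = np.r_[np.full(9, BACKGROUND), np.full(3, CELL)]
        with pytest.raises(TrainingError):
            train_classifier(make_table(x, labels), folds=5, seed=0)

    def test_training_is_deterministic(self, rng):
        x = rng.random((400, 3))
        labels = (rng.random(400) > 0.5).astype(np.uint8)
        t = make_table(x, labels)
        m1 = train_classifier(t, folds=5, seed=3, max_per_class=100)
        m2 = train_classifier(t, folds=5, seed=3, max_per_class=100)
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(m1.variances, m2.variances)
        assert m1.cv_accuracies == m2.cv_accuracies

    def test_subsampling_caps_class_sizes_and_balances_priors(self, rng):
        n_bg, n_cell, cap = 5000, 500, 300
        x = rng.random((n_bg + n_cell, 3))
        labels = np.r_[np.full(n_bg, BACKGROUND), np.full(n_cell, CELL)]
        model = train_classifier(make_table(x, labels), folds=5, seed=0, max_per_class=cap)
        assert model.n_train == (cap, cap)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])
        empirical = train_classifier(
            make_table(x, labels), folds=5, seed=0, max_per_class=cap,
            use_empirical_priors=True,
        )
        np.testing.assert_allclose(
            empirical.priors, [n_bg / (n_bg + n_cell), n_cell / (n_bg + n_cell)]
        )

    def test_variance_floor_applied(self):
        # zero within-class variance (quantized input) must not survive
        x = np.array([[0.5, 0.5, 0.5]] * 10 + [[0.9, 0.9, 0.9]] * 10)
        labels = np.r_[np.full(10, BACKGROUND), np.full(10, CELL)]
        model = train_classifier(make_table(x, labels), folds=5, seed=0)
        assert (model.variances > 0).all()


class TestPosteriors:
    def test_six_row_table_matches_bruteforce(self):
        priors = [0.4, 0.6]
        means = [[1.0, 0.2, 0.3], [3.0, 0.6, 0.7]]
        variances = [[0.5, 0.01, 0.04], [1.5, 0.09, 0.02]]
        model = PixelClassifierModel(
            priors=np.array(priors),
            means=np.array(means),
            variances=np.array(variances),
            n_train=(3, 3),
            cv_accuracies=(1.0,),
            seed=0,
        )
        x = np.array(
            [
                [1.1, 0.25, 0.33],
                [2.9, 0.55, 0.68],
                [0.0, 0.0, 0.0],
                [5.0, 1.0, 1.0],
                [2.0, 0.4, 0.5],
                [1.0, 0.6, 0.7],
            ]
        )
        expected = bruteforce_log_posteriors(priors, means, variances, x)
        np.testing.assert_allclose(model.log_posteriors(x), expected, atol=1e-10)

    def test_trained_model_matches_bruteforce(self, rng):
        x = rng.random((200, 3))
        labels = (x[:, 0] > 0.5).astype(np.uint8)
        model = train_classifier(make_table(x, labels), folds=5, seed=0)
        probe = rng.random((50, 3))
        expected = bruteforce_log_posteriors(
            model.priors, model.means, model.variances, probe
        )
        np.testing.assert_allclose(model.log_posteriors(probe), expected, atol=1e-10)

    def test_posteriors_normalize_to_one(self, rng):
        x = rng.random((300, 3)) * np.array([8.0, 1.0, 1.0])  # extreme e values too
        labels = (rng.random(300) > 0.5).astype(np.uint8)
        model = train_classifier(make_table(x, labels), folds=5, seed=0)
        post = np.exp(model.log_posteriors(rng.random((100, 3)) * 10))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestPrediction:
    def _model(self, priors, means=None, variances=None):
        return PixelClassifierModel(
            priors=np.asarray(priors, float),
            means=np.array(means if means is not None else [[0.0] * 3, [1.0] * 3]),
            variances=np.array(variances if variances is not None else [[0.1] * 3] * 2),
            n_train=(10, 10),
            cv_accuracies=(1.0,),
            seed=0,
        )

    def test_degenerate_cell_prior_claims_everything(self, rng):
        model = self._model([0.0, 1.0])
        img = IntensityImage(rng.random((40, 40)))
        mask = predict_mask(model, rng.random((40, 40)), rng.random((40, 40)), img)
        assert mask.mask.all()

    def test_likelihood_dominance_at_class_mean(self):
        # equal priors, equal variances; a pixel sitting on the CELL means
        model = self._model([0.5, 0.5], means=[[5.0, 0.9, 0.9], [1.0, 0.1, 0.2]])
        img = IntensityImage(np.full((40, 40), 0.2))
        ent = np.full((40, 40), 1.0)
        grad = np.full((40, 40), 0.1)
        mask = predict_mask(model, ent, grad, img)
        assert mask.mask.all()

    def test_exact_tie_goes_to_background(self):
        # mirror-symmetric classes and a probe exactly between them
        model = self._model([0.5, 0.5], means=[[0.0] * 3, [1.0] * 3])
        img = IntensityImage(np.full((40, 40), 0.5))
        mask = predict_mask(model, np.full((40, 40), 0.5), np.full((40, 40), 0.5), img)
        assert not mask.mask.any()


class TestSerialization:
    def test_text_roundtrip_is_exact(self, rng):
        x = rng.random((100, 3))
        labels = (rng.random(100) > 0.4).astype(np.uint8)
        model = train_classifier(make_table(x, labels), folds=5, seed=11)
        restored = PixelClassifierModel.from_text(model.to_text())
        np.testing.assert_array_equal(restored.means, model.means)
        np.testing.assert_array_equal(restored.variances, model.variances)
        np.testing.assert_array_equal(restored.priors, model.priors)
        assert restored.cv_accuracies == model.cv_accuracies
        assert restored.n_train == model.n_train
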