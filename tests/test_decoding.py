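"""Tests for temporal-generalization decoding of categorical and circular labels."""

import itertools

import numpy as np
import pytest

from silentwm.decoding import (FoldPlan, angular_accuracy, anova_select,
                               cross_generalize, fit_angle, fit_categorical,
                               score_auc, temporal_generalization)
from silentwm.synth import EpochGenSpec, gen_epochs


class TestAnovaSelect:
    def test_fraction_one_keeps_everything(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 7))
        y = rng.integers(0, 2, 40)
        assert anova_select(X, y, fraction=1.0).all()

    def test_planted_informative_features_selected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            y = rng.integers(0, 2, 200)
            X = rng.normal(size=(200, 10))
            X[:, :5] += 1.0 * y[:, None]
            mask = anova_select(X, y, fraction=0.5)
            hits += mask[:5].all()
        assert hits >= 48  # informative half recovered in >= 95% of draws

    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        X[:, 2] = 5.0
        y = rng.integers(0, 2, 30)
        mask = anova_select(X, y, fraction=0.75)
        assert not mask[2]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            anova_select(np.zeros((4, 2)), [0, 1, 0, 1], fraction=0.0)


class TestCategoricalDecoder:
    def test_perfectly_separated_classes_give_auc_one(self):
        X = np.r_[np.full((10, 1), -2.0), np.full((10, 1), 2.0)]
        y = np.r_[np.zeros(10), np.ones(10)]
        clf = fit_categorical(X, y)
        assert score_auc(clf.decision_function(X), y) == 1.0

    def test_auc_equals_concordant_pair_count(self):
        """Six-trial worked example against brute-force pair counting."""
        scores = np.array([0.3, -1.2, 0.8, 0.1, -0.4, 0.9])
        y = np.array([1, 0, 1, 0, 0, 1])
        pos = scores[y == 1]
        neg = scores[y == 0]
        concordant = sum(0.5 if p == n else float(p > n)
                         for p, n in itertools.product(pos, neg))
        assert score_auc(scores, y) == pytest.approx(
            concordant / (len(pos) * len(neg)))

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        assert score_auc(np.exp(scores) * 3 + 1, y) == pytest.approx(
            score_auc(scores, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_categorical(np.zeros((5, 2)), np.ones(5))


class TestAngleDecoder:
    def test_identity_feature_mapping_recovered(self):
        rng = np.random.default_rng(4)
        th = rng.uniform(-np.pi, np.pi, 300)
        X = np.column_stack([np.sin(th), np.cos(th)])
        pred = fit_angle(X, th).predict(X)
        err = np.abs(np.angle(np.exp(1j * (pred - th))))
        # C=1 regularization shrinks the coefficients very slightly
        assert err.max() < 5e-3

    def test_uninformative_features_near_chance(self):
        rng = np.random.default_rng(5)
        th = rng.uniform(-np.pi, np.pi, 2000)
        X = rng.normal(size=(2000, 4))
        pred = fit_angle(X[:1000], th[:1000]).predict(X[1000:])
        mae = np.abs(np.angle(np.exp(1j * (pred - th[1000:])))).mean()
        assert mae == pytest.approx(np.pi / 2, abs=0.12)

    def test_noisy_linear_code_beats_chance_and_improves_with_n(self):
        rng = np.random.default_rng(6)
        def run(n):
            th = rng.uniform(-np.pi, np.pi, 2 * n)
            X = np.column_stack([np.sin(th), np.cos(th)])
            X = X + rng.normal(0, 0.5, X.shape)
            pred = fit_angle(X[:n], th[:n]).predict(X[n:])
            return np.abs(np.angle(np.exp(1j * (pred - th[n:])))).mean()
        err_small, err_large = run(40), run(800)
        assert err_large < err_small < np.pi / 2
        assert err_large < 0.6

    def test_degenerate_angles_rejected(self):
        with pytest.raises(ValueError):
            fit_angle(np.zeros((5, 2)), np.full(5, 0.3))


class TestAngularAccuracy:
    def test_perfect_predictions(self):
        th = np.linspace(-3, 3, 50)
        assert angular_accuracy(th, th) == pytest.approx(np.pi / 2)

    def test_antipodal_predictions(self):
        th = np.linspace(-3, 3, 50)
        assert angular_accuracy(th + np.pi, th) == pytest.approx(-np.pi / 2)

    def test_uniform_random_predictions_near_zero(self):
        rng = np.random.default_rng(7)
        th = rng.uniform(-np.pi, np.pi, 4000)
        pred = rng.uniform(-np.pi, np.pi, 4000)
        assert angular_accuracy(pred, th) == pytest.approx(0.0, abs=0.05)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(8)
        th = rng.uniform(-np.pi, np.pi, 100)
        pred = th + rng.normal(0, 0.3, 100)
        assert angular_accuracy(pred + 0.9, th + 0.9) == pytest.approx(
            angular_accuracy(pred, th), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            angular_accuracy(np.zeros(3), np.zeros(4))


class TestFoldPlan:
    def test_stratified_folds_preserve_class_balance(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.zeros(60), np.ones(40)]
        rng.shuffle(y)
        plan = FoldPlan.build(y, k=5, seed=0)
        assert np.bincount(plan.assignments, minlength=5).sum() == 100
        for _, test in plan.splits():
            assert y[test].mean() == pytest.approx(0.4, abs=0.05)

    def test_every_trial_held_out_exactly_once(self):
        y = np.tile([0, 1], 30)
        plan = FoldPlan.build(y, k=5, seed=1)
        held = np.zeros(60, dtype=int)
        for _, test in plan.splits():
            held += test
        assert (held == 1).all()


@pytest.fixture(scope="module")
def coded_epochs():
    """Small epoch set with a sustained category code and an early angle code."""
    spec = EpochGenSpec(n_trials=120, n_channels=16, t_end=0.8, sfreq=25.0,
                        angle_window=(0.1, 0.5), cat_window=(0.3, 0.8),
                        angle_amp=1.2, cat_amp=1.2, noise_sd=1.0, seed=10)
    return gen_epochs(spec)


class TestTemporalGeneralization:
    def test_sustained_code_generalizes_in_block(self, coded_epochs):
        ep = coded_epochs
        gm = temporal_generalization(ep, ep.category_labels, metric="auc",
                                     seed=0)
        t = gm.train_times
        inside = (t >= 0.4) & (t <= 0.75)
        pre = t <= 0.2
        block = gm.scores[np.ix_(inside, inside)]
        assert block.mean() > 0.8           # square above-chance block
        assert gm.scores[np.ix_(pre, pre)].mean() == pytest.approx(0.5, abs=0.1)
        # off-diagonal generalization within the sustained window
        assert np.diag(block).mean() - block.mean() < 0.1

    def test_diagonal_matches_diagonal_only_run(self, coded_epochs):
        ep = coded_epochs
        full = temporal_generalization(ep, ep.category_labels, metric="auc",
                                       seed=0)
        diag = temporal_generalization(ep, ep.category_labels, metric="auc",
                                       seed=0, diagonal_only=True)
        np.testing.assert_allclose(np.diag(full.scores), np.diag(diag.scores))

    def test_transient_angle_code_confined_to_window(self, coded_epochs):
        ep = coded_epochs
        gm = temporal_generalization(ep, ep.angle_labels,
                                     metric="angular_accuracy", seed=0,
                                     diagonal_only=True)
        t = gm.train_times
        inside = (t >= 0.15) & (t <= 0.45)
        late = t >= 0.6
        assert gm.diagonal[inside].mean() > 0.35
        assert abs(gm.diagonal[late].mean()) < 0.25

    def test_shuffled_labels_score_at_chance(self, coded_epochs):
        ep = coded_epochs
        rng = np.random.default_rng(11)
        gm = temporal_generalization(ep, rng.permutation(ep.category_labels),
                                     metric="auc", seed=0, diagonal_only=True)
        assert np.nanmean(gm.diagonal) == pytest.approx(0.5, abs=0.06)


class TestCrossGeneralization:
    def test_shared_code_transfers_across_condition_sets(self):
        common = dict(n_trials=100, n_channels=12, t_end=0.6, sfreq=25.0,
                      angle_amp=0.0, angle_window=(0.1, 0.5),
                      cat_window=(0.2, 0.6), cat_amp=1.5,
                      noise_sd=1.0, code_seed=99)
        # same planted topography, independent trials and noise
        a = gen_epochs(EpochGenSpec(seed=12, **common))
        b = gen_epochs(EpochGenSpec(seed=21, **common))
        gm = cross_generalize(a, a.category_labels, b, b.category_labels,
                              metric="auc", seed=0)
        t = a.times
        inside = (t >= 0.3) & (t <= 0.55)
        assert gm.scores[np.ix_(inside, inside)].mean() > 0.8

    def test_shuffled_test_labels_at_chance(self, coded_epochs):
        ep = coded_epochs
        rng = np.random.default_rng(13)
        gm = cross_generalize(ep, ep.category_labels, ep,
                              rng.permutation(ep.category_labels),
                              metric="auc", seed=0)
        assert abs(gm.scores.mean() - 0.5) < 0.06

    def test_feature_dimension_mismatch_rejected(self, coded_epochs):
        ep = coded_epochs
        small = gen_epochs(EpochGenSpec(n_trials=30, n_channels=4, t_end=0.4,
                                        sfreq=25.0, angle_window=(0.1, 0.3),
                                        cat_window=(0.1, 0.4), seed=14))
        with pytest.raises(ValueError, match="channel"):
            cross_generalize(ep, ep.category_labels, small,
                             small.category_labels)
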