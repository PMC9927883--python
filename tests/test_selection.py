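"""Univariate screening, NCA weighting and step-down elimination."""

import numpy as np
import pytest

from conftest import make_gaussian_table
from eegsift.selection import (DiagonalNCA, NCAFeatureSelector, TTestScreen,
                               cv_accuracy, select_features, stepdown, zscore)


class TestScreen:
    def test_type_one_error_calibrated(self):
        # 500 null features: retention fraction inside the 95% binomial CI
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 500))
        y = np.array([0] * 100 + [1] * 100)
        frac = TTestScreen().fit(X, y).support_.mean()
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(frac - 0.05) < 1.96 * se

    def test_strong_effects_almost_always_retained(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 200))
        y = np.array([0] * 50 + [1] * 50)
        X[y == 1] += 2.0
        assert TTestScreen().fit(X, y).support_.mean() >= 0.99

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        X[:, 1] = 5.0
        y = np.array([0] * 20 + [1] * 20)
        with pytest.warns(RuntimeWarning):
            scr = TTestScreen().fit(X, y)
        assert not scr.support_[1]

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            TTestScreen().fit(X, np.zeros(10))


class TestZscore:
    def test_columns_standardized(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 3, (50, 4))
        Z = zscore(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 2))
        np.testing.assert_allclose(zscore(X), zscore(3.0 * X - 7.0), atol=1e-12)


class TestNca:
    def test_separating_feature_gets_max_weight(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 6))
        y = np.array([0] * 40 + [1] * 40)
        X[:, 2] = y * 6.0 + rng.normal(0, 0.1, 80)
        nca = DiagonalNCA(random_state=0).fit(zscore(X), y)
        assert np.argmax(nca.weights_) == 2

    def test_informative_features_recovered(self):
        recalls = []
        for seed in range(5):
            X, y = make_gaussian_table(seed)
            scr = TTestScreen().fit(X, y)
            keep = np.flatnonzero(scr.support_)
            sel = NCAFeatureSelector(n_reps=20, random_state=seed).fit(
                zscore(X[:, keep]), y)
            chosen = set(keep[sel.support_])
            recalls.append(len(chosen & set(range(10))) / 10)
        assert np.median(recalls) >= 0.8

    def test_null_table_weights_unstable(self):
        # without signal, no feature should dominate reproducibly
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 40))
        y = np.array([0] * 30 + [1] * 30)
        a = NCAFeatureSelector(n_reps=10, random_state=1).fit(zscore(X), y)
        b = NCAFeatureSelector(n_reps=10, random_state=2).fit(zscore(X), y)
        sa, sb = set(np.flatnonzero(a.support_)), set(np.flatnonzero(b.support_))
        jaccard = len(sa & sb) / max(len(sa | sb), 1)
        assert jaccard < 0.5

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            NCAFeatureSelector(n_reps=0).fit(np.zeros((10, 2)),
                                             np.array([0] * 5 + [1] * 5))


class TestCvAccuracy:
    def test_separable_classes_near_perfect(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((80, 4))
        y = np.array([0] * 40 + [1] * 40)
        X[y == 1] += 6.0
        assert cv_accuracy(X, y, reps=10, rng=0) >= 0.99

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 4))
        y = rng.permutation([0] * 50 + [1] * 50)
        acc = cv_accuracy(X, y, reps=20, rng=1)
        assert abs(acc - 0.5) < 1.96 * np.sqrt(0.25 / 100) * 2

    def test_reproducible_under_fixed_rng(self):
        X, y = make_gaussian_table(0, n_per_class=20, n_features=10)
        assert cv_accuracy(X, y, reps=5, rng=42) == cv_accuracy(X, y, reps=5, rng=42)


class TestStepdown:
    def test_duplicate_feature_eliminated(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(100)
        y = np.array([0] * 50 + [1] * 50)
        sig = base + y * 2.5
        X = np.column_stack([sig, sig, rng.standard_normal(100)])
        cols = ["a", "a_dup", "noise"]
        kept, trace = stepdown(zscore(X), y, cols, reps=10, rng=0)
        assert sum(c in ("a", "a_dup") for c in kept) == 1
        assert len(trace) >= 1

    def test_single_feature_returned_unchanged(self):
        X, y = make_gaussian_table(1, n_per_class=20, n_features=1, n_informative=1)
        kept, trace = stepdown(X, y, ["only"], reps=5, rng=0)
        assert kept == ["only"]


class TestSelectFeatures:
    def test_pipeline_monotone_and_recovers_signal(self):
        X, y = make_gaussian_table(2)
        res = select_features(X, y, nca_reps=20, cv_reps=5, stepdown_reps=5, seed=0)
        assert len(res.selected) <= len(res.nca_selected) <= len(res.screened) <= X.shape[1]
        assert res.validation_accuracy > 0.9
        assert set(res.selected) <= set(res.nca_selected) <= set(res.screened)
        planted = {f"f{i}" for i in range(10)}
        assert len(planted & set(res.nca_selected)) >= 8
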