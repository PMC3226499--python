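"""Fisher LDA, balanced accuracy, AUC, and stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from pvdc import (
    auc,
    balanced_accuracy,
    evaluate_features,
    lda_fit,
    lda_scores,
    stability_check,
    stepwise_select,
    stratified_folds,
)


class TestBalancedAccuracy:
    def test_perfect_confusion(self):
        assert balanced_accuracy(tp=10, fp=0, tn=20, fn=0) == 1.0

    def test_sens_spec_average_identity(self):
        # sens 0.9 (9/10), spec 0.7 (7/10) -> 0.8
        assert balanced_accuracy(tp=9, fp=3, tn=7, fn=1) == pytest.approx(0.8)

    def test_all_positive_predictor_on_balanced_labels(self):
        assert balanced_accuracy(tp=10, fp=10, tn=0, fn=0) == 0.5

    @pytest.mark.parametrize("counts", [(0, 5, 5, 0), (5, 0, 0, 5)])
    def test_empty_class_rejected(self, counts):
        tp, fp, tn, fn = counts
        with pytest.raises(ValueError):
            balanced_accuracy(tp, fp, tn, fn)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([5.0] * 8, [0, 1] * 4) == 0.5

    def test_matches_pair_counting_brute_force(self, rng):
        for _ in range(10):
            scores = rng.normal(size=30)
            y = (rng.random(30) < 0.5).astype(int)
            if y.sum() in (0, 30):
                y[0] = 1 - y[0]
            pos, neg = scores[y == 1], scores[y == 0]
            pairs = sum(
                1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos
                for n in neg
            )
            assert auc(scores, y) == pytest.approx(pairs / (len(pos) * len(neg)))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=50)
        y = np.array([0, 1] * 25)
        assert auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])


class TestLdaFit:
    def test_two_feature_case_matches_matrix_inverse(self, rng):
        """Coefficients equal direct 2×2 pooled-covariance inversion."""
        for _ in range(5):
            X0 = rng.normal(0, 1, size=(25, 2))
            X1 = rng.normal(1.5, 1, size=(25, 2))
            X = np.vstack([X0, X1])
            y = np.array([0] * 25 + [1] * 25)
            w, b = lda_fit(X, y)
            S = (np.cov(X0, rowvar=False, ddof=1) * 24
                 + np.cov(X1, rowvar=False, ddof=1) * 24) / 48
            S += 1e-6 * np.eye(2)
            mu0, mu1 = X0.mean(0), X1.mean(0)
            w_direct = np.linalg.inv(S) @ (mu1 - mu0)
            b_direct = -w_direct @ (mu0 + mu1) / 2
            assert np.allclose(w, w_direct, atol=1e-10)
            assert b == pytest.approx(b_direct, abs=1e-10)

    def test_direction_matches_sklearn_up_to_scale(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(1, 1, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        w, _ = lda_fit(X, y, ridge=0.0)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y).coef_.ravel()
        cos = w @ ref / (np.linalg.norm(w) * np.linalg.norm(ref))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_well_separated_gaussians_high_training_accuracy(self):
        rng = np.random.default_rng(42)
        X = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])[:, None]
        y = np.array([0] * 50 + [1] * 50)
        w, b = lda_fit(X, y)
        acc = ((lda_scores(X, w, b) >= 0).astype(int) == y).mean()
        assert acc >= 0.98  # Bayes error of N(0,1) vs N(5,1) ≈ 0.006

    def test_identical_class_means_no_signal(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = np.array([0, 1] * 50)
        w, _ = lda_fit(X, y)
        assert np.linalg.norm(w) < 1.0  # ridge-noise scale, no separation
        stats = evaluate_features(X, y, list("abc"), seed=0)
        assert 0.3 <= stats.ba_test <= 0.7

    def test_affine_rescaling_equivariance(self, rng):
        """Rescaling a feature leaves decision scores unchanged."""
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1, 1, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        w, b = lda_fit(X, y, ridge=0.0)
        X2 = X.copy()
        X2[:, 1] *= 37.0
        w2, b2 = lda_fit(X2, y, ridge=0.0)
        assert np.allclose(lda_scores(X, w, b), lda_scores(X2, w2, b2), atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.ones((10, 2)), [1] * 10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n > n_features"):
            lda_fit(np.eye(3), [0, 1, 1])


class TestStratifiedFolds:
    def test_partition_and_stratification(self):
        y = np.array([0] * 12 + [1] * 18)
        folds = stratified_folds(y, 5, seed=9)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(30))
        for f in folds:
            assert 0 < y[f].mean() < 1  # both classes in every fold

    def test_deterministic_given_seed(self):
        y = np.array([0, 1] * 20)
        a = stratified_folds(y, 5, seed=4)
        b = stratified_folds(y, 5, seed=4)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))


def _planted(seed=7, n=60, noise_features=20):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = pd.DataFrame(
        rng.normal(size=(n, noise_features + 1)),
        columns=[f"f{j}" for j in range(noise_features + 1)],
    )
    X["f5"] = y + rng.normal(scale=0.1, size=n)
    return X, y


class TestStepwiseSelect:
    def test_planted_separator_selected_first(self):
        X, y = _planted(seed=7)
        model = stepwise_select(X, y, folds=5, seed=7)
        assert model.features[0] == "f5"
        assert model.cv_stats.ba_test >= 0.95

    def test_pure_noise_selects_little_and_stays_near_chance(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame(
            rng.normal(size=(60, 20)), columns=[f"g{j}" for j in range(20)]
        )
        model = stepwise_select(X, y, folds=5, seed=7)
        assert len(model.features) <= 2
        assert 0.3 <= model.cv_stats.ba_test <= 0.7

    def test_duplicated_informative_feature_selected_once(self):
        X, y = _planted(seed=7)
        X = X.copy()
        X["f5_dup"] = X["f5"]
        model = stepwise_select(X, y, folds=5, seed=7)
        assert sum(f in ("f5", "f5_dup") for f in model.features) == 1
        assert model.features[0] == "f5"  # tie broken to lower column index

    def test_train_ba_not_below_test_ba_on_planted_data(self):
        X, y = _planted(seed=11)
        model = stepwise_select(X, y, folds=5, seed=11)
        assert model.cv_stats.ba_train >= model.cv_stats.ba_test - 0.05

    def test_small_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 3)))
        y = np.array([0] * 6 + [1] * 2)
        with pytest.raises(ValueError, match="each class"):
            stepwise_select(X, y, folds=5, seed=0)

    def test_fixed_seed_runs_bit_identical(self):
        X, y = _planted(seed=3)
        a = stepwise_select(X, y, folds=5, seed=13)
        b = stepwise_select(X, y, folds=5, seed=13)
        assert a.features == b.features
        assert a.cv_stats.as_dict() == b.cv_stats.as_dict()
        assert a.coefficients == b.coefficients

    def test_model_serializes_with_stats(self, tmp_path):
        import json

        X, y = _planted(seed=5)
        model = stepwise_select(X, y, folds=5, seed=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["features"][0] == "f5"
        assert set(payload["cv_stats"]) == {
            "ba_train", "ba_test", "sensitivity", "specificity", "auc"
        }


class TestStability:
    def test_fixed_seed_zero_dispersion(self):
        X, y = _planted(seed=2)
        report = stability_check(X, y, repeats=3, seed=8)
        assert report.fixed_seed_identical
        assert report.fixed_seed_ba_range == 0.0

    def test_across_seed_dispersion_small_on_planted_signal(self):
        X, y = _planted(seed=2)
        report = stability_check(X, y, repeats=5, seed=8)
        assert report.ba_std < 0.1

    def test_degenerate_small_sample_reports_gracefully(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        y = np.array([0] * 5 + [1] * 5)
        report = stability_check(X, y, repeats=2, seed=0, folds=2)
        assert np.isfinite(report.ba_std)
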