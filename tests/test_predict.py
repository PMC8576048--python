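"""Ridge closed form, inner grid search, nested LOOCV and evaluation."""

import dataclasses

import numpy as np
import pytest
from sklearn.linear_model import Ridge as SkRidge

from hemiconn.predict import (
    RidgeConfig, evaluate, fit_ridge, improvement_rate, inner_grid_search,
    nested_loocv, pearson_p_from_r, ridge_predict,
)
from hemiconn.selection import ForestConfig
from hemiconn.simulate import SubjectRecord


class TestImprovementRate:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(40, 10, 0.75), (50, 50, 0.0), (43.79, 15.35, (43.79 - 15.35) / 43.79)],
    )
    def test_formula(self, pre, post, expected):
        assert improvement_rate(pre, post) == pytest.approx(expected)

    def test_mean_of_ratios_is_not_ratio_of_means(self):
        # the rate computed from group-mean scores (~0.6495) intentionally
        # differs from a cohort's mean per-subject rate (~0.6562): the mean
        # of ratios is not the ratio of means
        assert improvement_rate(43.79, 15.35) == pytest.approx(0.64947, abs=1e-5)
        assert improvement_rate(43.79, 15.35) != pytest.approx(0.6562, abs=1e-3)

    def test_invalid_scores(self):
        with pytest.raises(ValueError):
            improvement_rate(0.0, 1.0)
        with pytest.raises(ValueError):
            improvement_rate(10.0, -1.0)


def closed_form_ridge(X, y, alpha, standardize):
    """Independent oracle: sklearn Ridge on the (optionally standardized)
    features, with the penalty rescaled from the mean-squared-error loss."""
    X = np.asarray(X, dtype=float)
    n = len(y)
    mean = X.mean(axis=0)
    scale = X.std(axis=0) if standardize else np.ones(X.shape[1])
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - mean) / scale
    sk = SkRidge(alpha=n * alpha / 2.0, fit_intercept=True, solver="cholesky")
    sk.fit(Xs, y)
    return sk.coef_, sk.intercept_ + float(sk.coef_ @ (-0.0 * mean))


class TestFitRidge:
    def test_hand_linear_algebra_oracle(self):
        # X = (1,2,3)', y = (1,2,3), alpha = 1, no standardization:
        # centered normal equations (2 + 3/2) theta = 2 -> theta = 4/7
        m = fit_ridge([[1.0], [2.0], [3.0]], [1.0, 2.0, 3.0], alpha=1.0,
                      standardize=False)
        assert m.coef[0] == pytest.approx(4 / 7, abs=1e-12)
        assert ridge_predict(m, [[2.0]])[0] == pytest.approx(2.0, abs=1e-12)
        assert ridge_predict(m, [[0.0]])[0] == pytest.approx(2 - 2 * 4 / 7, abs=1e-12)

    def test_ols_limit_interpolates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 4))
        y = rng.normal(size=4)
        m = fit_ridge(X, y, alpha=0.0, standardize=False)
        np.testing.assert_allclose(ridge_predict(m, X), y, atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = fit_ridge(X, y, alpha=1e6)
        assert np.all(np.abs(m.coef) < 1e-3)
        np.testing.assert_allclose(ridge_predict(m, X), np.mean(y), atol=1e-2)

    @pytest.mark.parametrize("standardize", [True, False])
    def test_matches_sklearn_on_random_problems(self, standardize):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            d = int(rng.integers(1, 8))
            X = rng.normal(size=(n, d)) * rng.uniform(0.5, 3.0, size=d)
            y = rng.normal(size=n)
            alpha = float(10 ** rng.uniform(-3, 3))
            m = fit_ridge(X, y, alpha, standardize=standardize)
            coef, _ = closed_form_ridge(X, y, alpha, standardize)
            np.testing.assert_allclose(m.coef, coef, atol=1e-8)

    def test_train_mse_nondecreasing_in_alpha(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        y = X[:, 0] + rng.normal(size=25)
        mses = []
        for alpha in np.logspace(-4, 4, 17):
            m = fit_ridge(X, y, alpha)
            mses.append(np.mean((ridge_predict(m, X) - y) ** 2))
        assert np.all(np.diff(mses) >= -1e-12)

    def test_empty_features_fall_back_to_mean(self):
        with pytest.warns(UserWarning, match="intercept-only"):
            m = fit_ridge(np.empty((5, 0)), [1.0, 2.0, 3.0, 4.0, 5.0], alpha=1.0)
        assert ridge_predict(m, np.empty((2, 0))) == pytest.approx([3.0, 3.0])


class TestInnerGridSearch:
    def test_single_point_grid(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        cfg = RidgeConfig(alpha_grid=(0.5,), max_iter_grid=(1000,), seed=0)
        assert inner_grid_search(X, y, cfg) == (0.5, 1000)

    def test_noise_free_linear_data_prefers_least_shrinkage(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        cfg = RidgeConfig(seed=1)
        alpha, max_iter = inner_grid_search(X, y, cfg)
        assert alpha == min(cfg.alpha_grid)
        assert max_iter == min(cfg.max_iter_grid)  # tie rule on the inert axis

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        cfg = RidgeConfig(seed=9)
        assert inner_grid_search(X, y, cfg) == inner_grid_search(X, y, cfg)

    def test_fold_reduction_warning(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(4, 2))
        y = rng.normal(size=4)
        with pytest.warns(UserWarning, match="reducing inner folds"):
            inner_grid_search(X, y, RidgeConfig(seed=0))


class TestEvaluate:
    def test_perfect_and_anti_correlation(self):
        v = np.array([0.1, 0.5, 0.3, 0.9, 0.2])
        r, p, r2 = evaluate(v, v)
        assert r == pytest.approx(1.0)
        assert p < 1e-6 and r2 == pytest.approx(1.0)
        r, _, _ = evaluate(-v, v)
        assert r == pytest.approx(-1.0)

    def test_printed_study_size_p_value(self):
        # r = 0.37 with 55 subjects -> p ~= 5e-3 via the t-transform,
        # matching the magnitude of the reported 5.68e-3
        p = pearson_p_from_r(0.37, 55)
        assert p == pytest.approx(5.4e-3, rel=0.05)
        assert abs(np.log10(p / 5.68e-3)) < 0.2

    def test_matches_permutation_null(self):
        """The t-transform p agrees with an empirical permutation p."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        r, p, _ = evaluate(x, y)
        n_perm = 2000
        more_extreme = 0
        for _ in range(n_perm):
            rp = np.corrcoef(x, y[rng.permutation(30)])[0, 1]
            more_extreme += abs(rp) >= abs(r)
        p_perm = (more_extreme + 1) / (n_perm + 1)
        se = np.sqrt(p * (1 - p) / n_perm)
        assert abs(p_perm - p) < 4 * se + 1e-3

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _records_with_rates(ids, rates):
    return [
        SubjectRecord(i, 50, "M", 40.0, float(40.0 * (1 - r)), float(r))
        for i, r in zip(ids, rates)
    ]


class TestNestedLOOCV:
    def test_recovers_planted_signal(self, tiny_planted_study):
        fm = tiny_planted_study["features"]
        cohort = tiny_planted_study["cohort"]
        res = nested_loocv(fm, cohort.records, ForestConfig(seed=1),
                           RidgeConfig(seed=1))
        assert res.pearson_r > 0.5
        assert len(res.subject_ids) == 12

    def test_bit_reproducible(self, tiny_planted_study):
        fm = tiny_planted_study["features"]
        cohort = tiny_planted_study["cohort"]
        a = nested_loocv(fm, cohort.records, ForestConfig(seed=2), RidgeConfig(seed=2))
        b = nested_loocv(fm, cohort.records, ForestConfig(seed=2), RidgeConfig(seed=2))
        np.testing.assert_array_equal(a.predicted_rate, b.predicted_rate)
        assert a.pearson_r == b.pearson_r

    def test_leakage_guard_mutation(self, tiny_planted_study):
        """Corrupting a held-out subject's outcome must not move its
        prediction (the outcome is never visible to that fold)."""
        fm = tiny_planted_study["features"]
        cohort = tiny_planted_study["cohort"]
        base = nested_loocv(fm, cohort.records, ForestConfig(seed=3), RidgeConfig(seed=3))
        mutated = list(cohort.records)
        victim = 5
        mutated[victim] = dataclasses.replace(
            mutated[victim], updrs_post=1.0, improvement_rate=0.999
        )
        res = nested_loocv(fm, mutated, ForestConfig(seed=3), RidgeConfig(seed=3))
        assert res.predicted_rate[victim] == base.predicted_rate[victim]

    def test_shuffled_outcomes_carry_no_positive_signal(self, tiny_planted_study):
        fm = tiny_planted_study["features"]
        cohort = tiny_planted_study["cohort"]
        rng = np.random.default_rng(10)
        rates = np.array([r.improvement_rate for r in cohort.records])
        shuffled = _records_with_rates(fm.subjects, rates[rng.permutation(len(rates))])
        res = nested_loocv(fm, shuffled, ForestConfig(seed=4), RidgeConfig(seed=4))
        # cross-validated correlation is negatively biased under the null, so
        # the defensible bound is one-sided: no spurious positive signal
        assert res.pearson_r < 0.3

    def test_duplicate_subjects_rejected(self, tiny_planted_study):
        fm = tiny_planted_study["features"]
        cohort = tiny_planted_study["cohort"]
        dup = list(cohort.records) + [cohort.records[0]]
        with pytest.raises(ValueError, match="duplicate"):
            nested_loocv(fm, dup, ForestConfig(seed=5), RidgeConfig(seed=5))

    def test_too_few_subjects_rejected(self, tiny_planted_study):
        from hemiconn.connectome import FeatureMatrix

        fm = tiny_planted_study["features"]
        small = FeatureMatrix(
            network=fm.network, subjects=fm.subjects[:5],
            edge_index=fm.edge_index, values=fm.values[:5],
        )
        with pytest.raises(ValueError, match="at least 10"):
            nested_loocv(small, tiny_planted_study["cohort"].records[:5],
                         ForestConfig(seed=0), RidgeConfig(seed=0))
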