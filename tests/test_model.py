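"""NIPALS PLS, latent-variable selection, PLS-DA, and evaluation metrics."""

import numpy as np
import pytest

from nirapple import (
    evaluate_regression,
    make_folds,
    misclassification_rate,
    outlier_filter,
    pls_fit,
    pls_predict,
    plsda_classify,
    plsda_fit,
    select_lv,
)
from nirapple.model import PlsModel, rmsecv_curve


def linear_data(n=40, p=12, n_informative=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    coef = np.zeros(p)
    coef[:n_informative] = rng.normal(size=n_informative)
    y = X @ coef + noise * rng.normal(size=n)
    return X, y, coef


class TestPlsFit:
    def test_rank_one_exact_fit(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=20)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        y = X[:, 2].copy()
        model = pls_fit(X, y, 1)
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_full_rank_equals_ols_pseudoinverse_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        model = pls_fit(X, y, 3)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = np.linalg.pinv(Xc) @ yc
        assert np.allclose(model.coefficients, b_ols, atol=1e-6)

    def test_matches_sklearn_nipals(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        for n_lv in (1, 3, 6):
            ours = pls_fit(X, y, n_lv)
            ref = sklearn_pls.PLSRegression(n_components=n_lv, scale=False).fit(
                X, y[:, None]
            )
            assert np.allclose(ours.coefficients, ref.coef_.ravel(), atol=1e-8)

    def test_invariant_to_balanced_duplication(self):
        X, y, _ = linear_data(seed=5, noise=0.1)
        a = pls_fit(X, y, 4)
        b = pls_fit(np.vstack([X, X]), np.concatenate([y, y]), 4)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-8)

    def test_scores_orthogonal(self):
        X, y, _ = linear_data(n=50, p=20, noise=0.2, seed=6)
        model = pls_fit(X, y, 8)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_degenerate_component_stops_early_with_warning(self):
        X = np.zeros((10, 4))
        X[:, 0] = np.arange(10.0)
        y = X[:, 0].copy()
        with pytest.warns(UserWarning):
            model = pls_fit(X, y, 3)
        assert model.n_lv < 3

    def test_input_validation(self):
        X, y, _ = linear_data()
        with pytest.raises(ValueError):
            pls_fit(X[:2], y[:2], 1)
        with pytest.raises(ValueError):
            pls_fit(X, y, 0)
        with pytest.raises(ValueError):
            pls_fit(X, y, X.shape[0])


class TestPlsPredict:
    def test_training_mean_maps_to_y_mean(self):
        X, y, _ = linear_data(noise=0.3, seed=7)
        model = pls_fit(X, y, 3)
        assert np.isclose(
            pls_predict(model, X.mean(axis=0)[None, :])[0], y.mean()
        )

    def test_noiseless_linear_recovery(self):
        X, y, _ = linear_data(n=60, p=10, noise=0.0, seed=8)
        model = pls_fit(X, y, 10)
        assert np.allclose(pls_predict(model, X), y, atol=1e-6)

    def test_invariant_to_null_space_perturbation(self):
        X, y, _ = linear_data(noise=0.2, seed=9)
        model = pls_fit(X, y, 3)
        b = model.coefficients
        rng = np.random.default_rng(0)
        v = rng.normal(size=b.size)
        v -= (v @ b) / (b @ b) * b  # project out b
        x = X[0]
        assert np.isclose(
            pls_predict(model, x[None, :])[0],
            pls_predict(model, (x + v)[None, :])[0],
        )

    def test_wavelength_count_mismatch(self):
        X, y, _ = linear_data()
        model = pls_fit(X, y, 2)
        with pytest.raises(ValueError):
            pls_predict(model, X[:, :5])


class TestSelectLv:
    def test_two_component_simulation(self):
        rng = np.random.default_rng(10)
        n, p = 80, 30
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        p1, p2 = rng.normal(size=p), rng.normal(size=p)
        X = np.outer(t1, p1) + np.outer(t2, p2)
        y = 2.0 * t1 - 1.5 * t2
        folds = make_folds(n, 10, seed=1)
        n_lv, curve = select_lv(X, y, max_lv=6, folds=folds)
        assert curve[1] < curve[0]
        model = pls_fit(X, y, n_lv)
        resid = y - model.predict(X)
        assert 1.0 - resid.var() / y.var() > 0.999

    def test_tied_minima_take_smaller_count(self):
        # duplicated informative column: the second component adds nothing,
        # so the curve flattens and the first minimizer wins
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        X = np.column_stack([x, x, x])
        y = x.copy()
        n_lv, curve = select_lv(X, y, max_lv=3, cv_folds=5, seed=2)
        assert n_lv == 1

    def test_max_lv_capped_at_training_size(self):
        X, y, _ = linear_data(n=12, p=30, noise=0.1)
        n_lv, curve = select_lv(X, y, max_lv=20, cv_folds=4, seed=0)
        assert curve.size <= 8  # smallest training fold minus one

    def test_curve_reproducible_under_fold_seed(self):
        X, y, _ = linear_data(n=50, p=20, noise=0.4, seed=12)
        folds = make_folds(50, 10, seed=5)
        _, c1 = select_lv(X, y, max_lv=8, folds=folds)
        _, c2 = select_lv(X, y, max_lv=8, folds=folds)
        assert np.array_equal(c1, c2)

    def test_rmsecv_definition_on_single_fold_pair(self):
        # 2-fold CV oracle computed by hand with two explicit fits
        X, y, _ = linear_data(n=20, p=5, noise=0.3, seed=13)
        folds = make_folds(20, 2, seed=3)
        curve = rmsecv_curve(X, y, 2, folds)
        sse = 0.0
        for fold in (0, 1):
            val = folds.fold_of_sample == fold
            model = pls_fit(X[~val], y[~val], 2)
            sse += np.sum((model.predict(X[val]) - y[val]) ** 2)
        assert np.isclose(curve[1], np.sqrt(sse / 20.0))


class TestPlsda:
    def make_class_data(self, n_per_class=12, seed=0):
        rng = np.random.default_rng(seed)
        weeks = np.repeat(np.arange(1, 8), n_per_class)
        profile = rng.normal(size=25)
        X = np.outer(weeks.astype(float), profile)
        X += 0.01 * rng.normal(size=X.shape)
        return X, weeks

    def test_separable_weeks_classified_exactly(self):
        X, weeks = self.make_class_data()
        model = plsda_fit(X, weeks, 2)
        assert misclassification_rate(weeks, plsda_classify(model, X)) == 0.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError):
            plsda_fit(X, np.full(10, 3), 1)

    def test_midpoint_rounding_and_clamping(self):
        # hand-built single-variable model: prediction equals the input
        model = PlsModel(
            n_lv=1,
            x_mean=np.zeros(1),
            y_mean=0.0,
            weights=np.ones((1, 1)),
            x_loadings=np.ones((1, 1)),
            y_loadings=np.ones(1),
            scores=np.zeros((1, 1)),
            coefficients=np.ones(1),
            class_range=(1, 7),
        )
        cont = np.array([[3.4], [3.6], [3.5], [0.2], [7.9]])
        assert plsda_classify(model, cont).tolist() == [3, 4, 4, 1, 7]

    def test_deterministic(self):
        X, weeks = self.make_class_data(seed=4)
        a = plsda_fit(X, weeks, 3)
        b = plsda_fit(X, weeks, 3)
        assert np.array_equal(a.coefficients, b.coefficients)


class TestMetrics:
    def test_hand_arithmetic_rmsep(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.1, 1.9, 3.2])
        X, yc, _ = linear_data(n=10, p=3, noise=0.0, seed=14)
        model = pls_fit(X, yc, 2)
        # evaluate_regression on exact predictions via an identity trick is
        # clumsy; check the RMSE composition directly instead
        from nirapple.metrics import pearson, rmse

        assert np.isclose(rmse(y, yhat), np.sqrt(0.06 / 3.0))
        assert pearson(y, y) == 1.0

    def test_perfect_and_anti_correlated_predictions(self):
        from nirapple.metrics import pearson, rmse

        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert np.isclose(pearson(y, y[::-1]), -1.0)

    def test_zero_variance_correlation_missing_with_warning(self):
        from nirapple.metrics import pearson

        with pytest.warns(UserWarning):
            assert pearson(np.ones(5), np.arange(5.0)) is None

    def test_evaluate_regression_composition(self):
        X, y, _ = linear_data(n=30, p=8, noise=0.2, seed=15)
        model = pls_fit(X[:20], y[:20], 4)
        m = evaluate_regression(model, X[:20], y[:20], X[20:], y[20:])
        yhat = model.predict(X[20:])
        assert np.isclose(m.rmsep, np.sqrt(np.mean((yhat - y[20:]) ** 2)))
        assert np.isclose(m.rp, np.corrcoef(yhat, y[20:])[0, 1])
        assert -1.0 <= m.rc <= 1.0

    @pytest.mark.parametrize(
        "mismatches, n, expected",
        [(9, 28, 0.321), (0, 10, 0.0), (10, 10, 1.0)],
    )
    def test_misclassification_rate(self, mismatches, n, expected):
        true = np.arange(n) % 7 + 1
        pred = true.copy()
        pred[:mismatches] = pred[:mismatches] % 7 + 1
        assert round(misclassification_rate(true, pred), 3) == expected

    def test_misclassification_validation(self):
        with pytest.raises(ValueError):
            misclassification_rate(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            misclassification_rate(np.array([1]), np.array([1, 2]))


class TestOutlierFilter:
    def make_refs(self, values):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "variety": "Akesu",
                "temperature_c": 1.0,
                "week": 1,
                "ssc_brix": values,
                "firmness_n": 9.0,
            }
        )

    def test_null_normal_rarely_filtered(self):
        removals = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            refs = self.make_refs(rng.normal(14.0, 0.7, size=200))
            kept = outlier_filter(refs, "ssc_brix", alpha=0.05)
            removals += len(kept) < 200
        assert removals <= 2  # type-I behavior: >=90% of seeds untouched

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(3)
        values = rng.normal(14.0, 0.7, size=100)
        values[17] = 14.0 + 10 * 0.7
        refs = self.make_refs(values)
        kept = outlier_filter(refs, "ssc_brix", alpha=0.05)
        assert "s17" not in set(kept["sample_id"])

    def test_small_normal_set_unchanged(self):
        rng = np.random.default_rng(8)
        refs = self.make_refs(rng.normal(14.0, 0.5, size=12))
        kept = outlier_filter(refs, "ssc_brix", alpha=0.05)
        assert len(kept) == 12
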