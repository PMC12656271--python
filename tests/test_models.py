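"""Stacked regression: tuning, out-of-fold meta-features, nested CV."""

import numpy as np
import pandas as pd
import pytest

from maizelai import StackedRegressor, fit_stack, make_meta_features, tune_base
from maizelai.models import (
    DEFAULT_GRIDS, MINIMAL_GRIDS, nested_cv_evaluate,
)


class TestTuneBase:
    def test_single_point_grid_is_selected(self, tabular_linear):
        X, y = tabular_linear
        grid = {"svr__C": [10], "svr__epsilon": [0.1], "svr__gamma": ["scale"]}
        _, best, _ = tune_base("svm", X, y, grid, seed=0)
        assert best == {"svr__C": 10, "svr__epsilon": 0.1, "svr__gamma": "scale"}

    def test_plsr_exact_fit_on_noiseless_linear_data(self, tabular_linear):
        X, y = tabular_linear
        fitted, best, rmse = tune_base("plsr", X, y, seed=0)
        assert rmse < 1e-6
        assert np.allclose(fitted.predict(X), y, atol=1e-6)

    def test_deterministic_best_point(self, tabular_linear):
        X, y = tabular_linear
        yn = y + np.random.default_rng(1).normal(0, 0.5, len(y))
        _, b1, _ = tune_base("gbdt", X, yn, MINIMAL_GRIDS["gbdt"], seed=3)
        _, b2, _ = tune_base("gbdt", X, yn, MINIMAL_GRIDS["gbdt"], seed=3)
        assert b1 == b2

    def test_constant_response_raises(self, tabular_linear):
        X, _ = tabular_linear
        with pytest.raises(ValueError):
            tune_base("plsr", X, np.ones(len(X)), seed=0)

    def test_tuned_point_lies_in_declared_grid(self, tabular_linear):
        X, y = tabular_linear
        yn = y + np.random.default_rng(2).normal(0, 0.3, len(y))
        grid = {k: v[:2] for k, v in DEFAULT_GRIDS["svm"].items()}
        _, best, _ = tune_base("svm", X, yn, grid, inner_cv=3, seed=0)
        for k, v in best.items():
            assert v in grid[k]


class TestMetaFeatures:
    def test_shape_and_fold_bookkeeping(self, tabular_linear):
        X, y = tabular_linear
        Z, fold_id = make_meta_features(X, y, ("plsr", "svm"), MINIMAL_GRIDS, k=5, seed=0)
        assert Z.shape == (len(y), 2)
        assert not np.isnan(Z).any()
        assert set(fold_id) == set(range(5))

    def test_out_of_fold_property(self, tabular_linear):
        # a base trained without fold f cannot depend on fold-f labels
        X, y = tabular_linear
        Z1, fold_id = make_meta_features(X, y, ("plsr", "svm"), MINIMAL_GRIDS, k=4, seed=1)
        y2 = y.copy()
        corrupt = fold_id == 0
        y2[corrupt] = 77.0
        Z2, _ = make_meta_features(X, y2, ("plsr", "svm"), MINIMAL_GRIDS, k=4, seed=1)
        np.testing.assert_allclose(Z1[corrupt], Z2[corrupt], atol=1e-10)

    def test_plsr_column_recovers_noiseless_linear_response(self, tabular_linear):
        X, y = tabular_linear
        Z, _ = make_meta_features(X, y, ("plsr", "svm"), MINIMAL_GRIDS, k=5, seed=0)
        assert np.max(np.abs(Z[:, 0] - y)) < 1e-6

    def test_k_below_two_raises(self, tabular_linear):
        X, y = tabular_linear
        with pytest.raises(ValueError):
            make_meta_features(X, y, ("plsr", "svm"), MINIMAL_GRIDS, k=1)


class TestStackedRegressor:
    def test_exact_fit_limit(self, tabular_linear):
        X, y = tabular_linear
        model = fit_stack(X, y, ("plsr", "svm"), grids="minimal", seed=0)
        pred = model.predict(X)
        ss = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss >= 0.999

    def test_identical_meta_features_lasso_drops_one(self):
        # L1 fusion of two identical base predictions recovers y while
        # shrinking the redundant weight to zero
        from sklearn.linear_model import LassoCV
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        y = np.random.default_rng(0).uniform(1, 5, 80)
        Z = np.column_stack([y, y])
        meta = Pipeline([
            ("scale", StandardScaler()),
            ("lasso", LassoCV(cv=5, random_state=0, max_iter=50000)),
        ]).fit(Z, y)
        np.testing.assert_allclose(meta.predict(Z), y, atol=0.05)
        assert min(np.abs(meta.named_steps["lasso"].coef_)) < 1e-8

    def test_bitwise_deterministic_refit(self, tabular_linear):
        X, y = tabular_linear
        yn = y + np.random.default_rng(4).normal(0, 0.4, len(y))
        m1 = fit_stack(X, yn, ("plsr", "gbdt"), grids="minimal", seed=9)
        m2 = fit_stack(X, yn, ("plsr", "gbdt"), grids="minimal", seed=9)
        np.testing.assert_array_equal(m1.meta_coefficients_, m2.meta_coefficients_)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_schema_validation_on_predict(self, tabular_linear):
        X, y = tabular_linear
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        model = fit_stack(df, y, ("plsr", "svm"), grids="minimal", seed=0)
        with pytest.raises(ValueError, match="schema"):
            model.predict(df.drop(columns=["f0"]))
        with pytest.raises(ValueError, match="schema"):
            model.predict(df.assign(extra=1.0))
        # reordered columns are accepted and realigned
        np.testing.assert_allclose(
            model.predict(df[df.columns[::-1]]), model.predict(df), atol=1e-12
        )

    def test_row_permutation_equivariance_and_single_row(self, tabular_linear):
        X, y = tabular_linear
        model = fit_stack(X, y, ("plsr", "svm"), grids="minimal", seed=0)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(model.predict(X[perm]), model.predict(X)[perm])
        assert model.predict(X[:1]).shape == (1,)

    def test_invalid_pair_rejected(self, tabular_linear):
        X, y = tabular_linear
        with pytest.raises(ValueError):
            fit_stack(X, y, ("svm", "plsr"), grids="minimal")
        with pytest.raises(ValueError):
            StackedRegressor(ml="plsr").fit(X, y)

    def test_sklearn_get_set_params_roundtrip(self):
        from sklearn.base import clone

        m = StackedRegressor(ml="rf", grids="fast", meta_k=4, random_state=1)
        assert clone(m).get_params() == m.get_params()


class TestNestedCV:
    def test_exact_fit_limit_aggregate(self, tabular_linear):
        X, y = tabular_linear
        res = nested_cv_evaluate(X, y, ml="svm", grids="minimal", outer=5, seed=0)
        assert res.aggregate["r2_mean"] >= 0.999

    def test_deterministic_fold_metrics(self, tabular_linear):
        X, y = tabular_linear
        yn = y + np.random.default_rng(5).normal(0, 0.4, len(y))
        r1 = nested_cv_evaluate(X, yn, ml="svm", grids="minimal", outer=5, seed=2)
        r2 = nested_cv_evaluate(X, yn, ml="svm", grids="minimal", outer=5, seed=2)
        pd.testing.assert_frame_equal(r1.fold_metrics, r2.fold_metrics)

    def test_outer_fold_predictions_invariant_to_own_label_corruption(self, tabular_linear):
        # the no-leakage guarantee: fold-f predictions cannot change when
        # fold-f labels are corrupted, because no fit ever saw them
        X, y = tabular_linear
        yn = y + np.random.default_rng(6).normal(0, 0.3, len(y))
        r1 = nested_cv_evaluate(X, yn, ml="svm", grids="minimal", outer=4, seed=3)
        f0 = r1.fold_of_sample == 0
        y2 = yn.copy()
        y2[f0] = -50.0
        r2 = nested_cv_evaluate(X, y2, ml="svm", grids="minimal", outer=4, seed=3)
        np.testing.assert_array_equal(r2.fold_of_sample, r1.fold_of_sample)
        np.testing.assert_allclose(r2.predictions[f0], r1.predictions[f0], atol=1e-10)
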