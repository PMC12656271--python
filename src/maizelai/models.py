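"""Stacked PLSR + machine-learning regression with nested cross-validation.

The stack pairs a partial-least-squares regressor (latent-variable linear
model, robust to multicollinearity) with one nonlinear learner (SVM, RF or
GBDT).  Out-of-fold predictions of the two tuned base learners form a
two-column meta-feature matrix on which an L1-penalised (Lasso) meta-model
is trained; for deployment both bases are re-tuned and refitted on the
full training set.  Hyperparameters are chosen by exhaustive grid search
minimising inner-CV RMSE, and generalisation is measured by an outer
(repeated) K-fold loop in which screening, tuning and stacking are all
re-run per fold so no held-out information leaks into any fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

LEARNERS = ("plsr", "svm", "rf", "gbdt")

# Grid values lie inside the published tuning ranges:
# GBDT learning_rate 0.05-0.2, depth 3-5, min_leaf 2-5, trees 100-300;
# RF trees 100-300, max-feature ratio 0.3-0.8; SVM C 0.1-100, eps 0.01-1.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gbdt": {
        "learning_rate": [0.05, 0.1, 0.2],
        "max_depth": [3, 4, 5],
        "min_samples_leaf": [2, 3, 5],
        "n_estimators": [100, 200],
        "subsample": [0.8, 1.0],
    },
    "rf": {
        "n_estimators": [100, 200, 300],
        "max_features": [0.3, 0.5, 0.8],
        "max_depth": [None, 5, 10],
        "min_samples_leaf": [1, 2, 5],
        "min_samples_split": [2, 5],
    },
    "svm": {
        "svr__C": [0.1, 1, 10, 100],
        "svr__epsilon": [0.01, 0.1, 0.5, 1],
        "svr__gamma": ["scale", 0.01, 0.1, 1],
    },
}

# Reduced grids for desk-scale runs; values stay inside the same ranges.
FAST_GRIDS: dict[str, dict[str, list]] = {
    "gbdt": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [3, 5],
        "min_samples_leaf": [2],
        "n_estimators": [100],
        "subsample": [1.0],
    },
    "rf": {
        "n_estimators": [100],
        "max_features": [0.3, 0.8],
        "max_depth": [None, 5],
        "min_samples_leaf": [2],
        "min_samples_split": [2],
    },
    "svm": {
        "svr__C": [1, 10, 100],
        "svr__epsilon": [0.01, 0.1],
        "svr__gamma": ["scale", 0.1],
    },
}

#: single-point grids for smoke tests and null-signal controls
MINIMAL_GRIDS: dict[str, dict[str, list]] = {
    "gbdt": {
        "learning_rate": [0.1],
        "max_depth": [3],
        "min_samples_leaf": [2],
        "n_estimators": [100],
        "subsample": [1.0],
    },
    "rf": {
        "n_estimators": [100],
        "max_features": [0.5],
        "max_depth": [None],
        "min_samples_leaf": [2],
        "min_samples_split": [2],
    },
    "svm": {"svr__C": [10], "svr__epsilon": [0.1], "svr__gamma": ["scale"]},
}

_GRID_SETS = {"default": DEFAULT_GRIDS, "fast": FAST_GRIDS, "minimal": MINIMAL_GRIDS}


class _PLS(PLSRegression):
    """PLSRegression predicting 1-D targets as 1-D arrays."""

    def predict(self, X):  # noqa: D102
        return np.asarray(super().predict(X)).ravel()


def _make_estimator(learner: str, seed: int | None):
    if learner == "plsr":
        return _PLS()
    if learner == "svm":
        return Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    if learner == "rf":
        return RandomForestRegressor(random_state=seed)
    if learner == "gbdt":
        return GradientBoostingRegressor(random_state=seed)
    raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


def _grid_for(learner: str, grids, n_features: int, n_samples: int) -> dict[str, list]:
    """Resolve a grid-set name/dict (or an explicit parameter grid) for one learner."""
    if grids is None:
        grids = "default"
    if isinstance(grids, str):
        grids = _GRID_SETS[grids]
    is_grid_set = bool(set(grids) & set(LEARNERS))
    if learner == "plsr":
        if is_grid_set and "plsr" in grids:
            return grids["plsr"]
        if not is_grid_set and grids:
            return grids
        # searched up to min(15, p, n-1) latent components
        hi = max(1, min(15, n_features, n_samples - 1))
        return {"n_components": list(range(1, hi + 1))}
    if is_grid_set:
        return grids[learner]
    return grids  # already a parameter grid for this learner


def tune_base(learner: str, X, y, grid=None, inner_cv: int = 5, seed: int | None = None):
    """Exhaustive grid search by inner-CV mean RMSE; refit on all of X.

    Returns ``(fitted estimator, best grid point, best cv rmse)``.  Ties
    are broken by grid order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0:
        raise ValueError("X must be non-empty")
    if np.std(y) == 0:
        raise ValueError("degenerate constant response")
    grid = _grid_for(learner, grid, X.shape[1], X.shape[0])
    est = _make_estimator(learner, seed)
    n_points = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_points == 1:
        params = {k: v[0] for k, v in grid.items()}
        fitted = clone(est).set_params(**params).fit(X, y)
        resid = fitted.predict(X) - y
        return fitted, params, float(np.sqrt(np.mean(resid**2)))
    cv = KFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    search = GridSearchCV(
        est, grid, scoring="neg_root_mean_squared_error", cv=cv, refit=True, n_jobs=None
    )
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_), float(-search.best_score_)


def make_meta_features(
    X, y, base_learners=("plsr", "gbdt"), grids="default",
    k: int = 5, inner_cv: int = 5, seed: int | None = None,
):
    """Out-of-fold base-learner predictions as an (n, 2) meta-feature matrix.

    For each of ``k`` folds both bases are tuned and fitted on the other
    k-1 folds only, so every sample's meta-features come from models that
    never saw it.  Also returns the fold id of each sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    Z = np.full((len(y), len(base_learners)), np.nan)
    fold_id = np.full(len(y), -1, dtype=int)
    for f, (tr, te) in enumerate(folds.split(X)):
        if len(te) < 1 or len(tr) < 2:
            raise ValueError("fold too small")
        for b, learner in enumerate(base_learners):
            fitted, _, _ = tune_base(learner, X[tr], y[tr], grids, inner_cv, seed)
            Z[te, b] = fitted.predict(X[te])
        fold_id[te] = f
    return Z, fold_id


class StackedRegressor(RegressorMixin, BaseEstimator):
    """PLSR + one nonlinear learner fused by a Lasso meta-model.

    Parameters
    ----------
    ml : "svm" | "rf" | "gbdt"
        The nonlinear base learner paired with PLSR.
    grids : "default" | "fast" | "minimal" | dict
        Hyperparameter grids for the base learners.
    meta_k : folds used to build out-of-fold meta-features.
    inner_cv : folds of the grid-search RMSE estimate.
    random_state : root seed for every stochastic choice.

    Fitted attributes follow sklearn conventions: ``base_plsr_``,
    ``base_ml_``, ``meta_model_``, ``tuned_params_``,
    ``meta_coefficients_`` (intercept + one weight per base, on the
    original prediction scale), ``meta_features_``, ``feature_names_in_``.
    """

    def __init__(self, ml="gbdt", grids="default", meta_k=5, inner_cv=5, random_state=None):
        self.ml = ml
        self.grids = grids
        self.meta_k = meta_k
        self.inner_cv = inner_cv
        self.random_state = random_state

    def _check_X(self, X, fitting: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if fitting:
                self.feature_names_in_ = np.asarray(names, dtype=object)
            else:
                expected = list(getattr(self, "feature_names_in_", names))
                if set(names) != set(expected):
                    missing = set(expected) - set(names)
                    extra = set(names) - set(expected)
                    raise ValueError(
                        f"feature schema mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
                    )
                X = X[expected]
            return np.asarray(X, dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        if self.ml not in ("svm", "rf", "gbdt"):
            raise ValueError(f"ml must be one of svm/rf/gbdt, got {self.ml!r}")
        Xa = self._check_X(X, fitting=True)
        y = np.asarray(y, dtype=float)
        if Xa.ndim != 2 or len(Xa) != len(y):
            raise ValueError("X must be 2-D with one row per y")
        if np.std(y) == 0:
            raise ValueError("degenerate constant response")
        seed = self.random_state
        pair = ("plsr", self.ml)
        Z, fold_id = make_meta_features(
            Xa, y, pair, self.grids, self.meta_k, self.inner_cv, seed
        )
        meta = Pipeline([
            ("scale", StandardScaler()),
            ("lasso", LassoCV(cv=self.meta_k, random_state=seed, max_iter=50000)),
        ])
        meta.fit(Z, y)
        self.meta_model_ = meta
        self.meta_features_ = Z
        self.meta_fold_id_ = fold_id
        # deployment bases: tuned and refitted on all data
        self.tuned_params_ = {}
        self.base_plsr_, self.tuned_params_["plsr"], _ = tune_base(
            "plsr", Xa, y, self.grids, self.inner_cv, seed
        )
        self.base_ml_, self.tuned_params_[self.ml], _ = tune_base(
            self.ml, Xa, y, self.grids, self.inner_cv, seed
        )
        lasso = meta.named_steps["lasso"]
        scale = meta.named_steps["scale"]
        w = lasso.coef_ / scale.scale_
        b = lasso.intercept_ - float(np.sum(lasso.coef_ * scale.mean_ / scale.scale_))
        self.meta_coefficients_ = np.concatenate([[b], w])
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "meta_model_"):
            raise ValueError("StackedRegressor is not fitted")
        Xa = self._check_X(X, fitting=False)
        Z = np.column_stack([self.base_plsr_.predict(Xa), self.base_ml_.predict(Xa)])
        return np.asarray(self.meta_model_.predict(Z)).ravel()


def fit_stack(X, y, pair=("plsr", "gbdt"), grids="default", meta_k=5,
              inner_cv=5, seed=None) -> StackedRegressor:
    """Functional wrapper: fit a PLSR + ML stack on (X, y)."""
    if tuple(pair)[0] != "plsr":
        raise ValueError("pair must start with 'plsr'")
    model = StackedRegressor(
        ml=tuple(pair)[1], grids=grids, meta_k=meta_k, inner_cv=inner_cv, random_state=seed
    )
    return model.fit(X, y)


@dataclass
class NestedCVResult:
    fold_metrics: pd.DataFrame
    predictions: np.ndarray
    fold_of_sample: np.ndarray
    aggregate: dict[str, float] = field(default_factory=dict)


def _outer_splitter(outer, seed):
    if outer == "10-fold":
        return KFold(n_splits=10, shuffle=True, random_state=seed)
    if outer == "5x2":
        return RepeatedKFold(n_splits=5, n_repeats=2, random_state=seed)
    if isinstance(outer, int):
        return KFold(n_splits=outer, shuffle=True, random_state=seed)
    return outer  # pre-built splitter or explicit fold list


def nested_cv_evaluate(
    X, y, ml="gbdt", grids="default", outer="10-fold",
    meta_k=5, inner_cv=5, seed=None,
    screen_groups: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    screen_top_k: dict[str, int] | None = None,
) -> NestedCVResult:
    """Outer-CV estimate of the full screened-and-tuned stacking procedure.

    Per outer training fold the whole pipeline — optional per-group
    Pearson screening, grid-search tuning, out-of-fold stacking — is
    re-run from scratch; outer test folds contribute only predictions.
    """
    from .evaluation import metrics  # local import to avoid a cycle

    Xdf = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    splitter = _outer_splitter(outer, seed)
    split_iter = splitter.split(Xdf) if hasattr(splitter, "split") else splitter
    preds = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    rows = []
    for f, (tr, te) in enumerate(split_iter):
        Xtr, ytr = Xdf.iloc[tr], y[tr]
        cols = list(Xdf.columns)
        if screen_groups is not None:
            from .selection import screen_features

            try:
                _, retained = screen_features(
                    Xtr, ytr, alpha=alpha, feature_groups=screen_groups,
                    top_k=screen_top_k,
                )
                cols = [c for grp in screen_groups for c in retained.get(grp, [])]
            except ValueError:
                # null-signal folds: keep everything rather than fail
                cols = list(Xdf.columns)
        model = StackedRegressor(
            ml=ml, grids=grids, meta_k=meta_k, inner_cv=inner_cv, random_state=seed
        )
        model.fit(Xtr[cols], ytr)
        p = model.predict(Xdf.iloc[te][cols])
        preds[te] = p
        fold_of[te] = f
        rep = metrics(y[te], p, split_label=f"fold{f}")
        rows.append({"fold": f, "r2": rep.r2, "rmse": rep.rmse, "mae": rep.mae, "n": rep.n})
    fold_df = pd.DataFrame(rows)
    agg = {
        f"{m}_{s}": float(getattr(fold_df[m], s)())
        for m in ("r2", "rmse", "mae") for s in ("mean", "std")
    }
    return NestedCVResult(fold_df, preds, fold_of, agg)
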