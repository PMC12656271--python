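"""Pearson screening of candidate features against LAI.

Features are retained when their two-sided correlation test gives
p < alpha (default 0.05, no multiple-testing correction — a documented
statistical caveat of the screening design) and ranked by |r|.  Screening
is applied inside training folds during cross-validated evaluation so no
held-out information influences the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class ScreeningResult:
    feature_name: str
    group: str
    r: float
    p_value: float
    retained: bool


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def screen_features(
    feature_table: pd.DataFrame,
    lai,
    alpha: float = 0.05,
    feature_groups: dict[str, list[str]] | None = None,
    top_k: dict[str, int] | None = None,
    fixed_lists: dict[str, list[str]] | None = None,
):
    """Per-group significance screening.

    Returns ``(report, retained)``: a DataFrame of per-feature results and
    a dict mapping each group to its retained feature names ranked by |r|
    descending.  ``top_k`` caps a group's retained list; ``fixed_lists``
    overrides a group's retention with an explicit list (the replication
    configuration, where the retained sets are fixed a priori).  A group
    with no significant feature raises unless a fixed list covers it.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    y = np.asarray(lai, dtype=float)
    if feature_groups is None:
        feature_groups = {"all": list(feature_table.columns)}
    top_k = top_k or {}
    fixed_lists = fixed_lists or {}

    rows: list[ScreeningResult] = []
    retained: dict[str, list[str]] = {}
    for group, names in feature_groups.items():
        scored = []
        for name in names:
            x = feature_table[name].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0:
                rows.append(ScreeningResult(name, group, float("nan"), float("nan"), False))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            keep = bool(p < alpha)
            scored.append((name, float(r), float(p), keep))
        if group in fixed_lists:
            keep_set = list(fixed_lists[group])
            rows.extend(
                ScreeningResult(n, group, r, p, n in keep_set) for n, r, p, _ in scored
            )
            retained[group] = keep_set
            continue
        scored.sort(key=lambda t: (-abs(t[1]), t[0]))
        kept = [n for n, r, p, keep in scored if keep]
        if group in top_k:
            kept = kept[: top_k[group]]
        rows.extend(
            ScreeningResult(n, group, r, p, n in kept) for n, r, p, _ in scored
        )
        if not kept:
            raise ValueError(f"no feature retained in group {group!r}")
        retained[group] = kept
    report = pd.DataFrame([r.__dict__ for r in rows])
    return report, retained


class CorrelationScreener(TransformerMixin, BaseEstimator):
    """sklearn transformer keeping features significantly correlated with y.

    Parameters
    ----------
    alpha : significance level of the per-feature correlation test.
    top_k : optional cap on the number of retained features (by |r|).
    fallback_best : when no feature passes, keep the single best-|r|
        feature instead of failing (keeps CV pipelines defined on null
        data).
    """

    def __init__(self, alpha: float = 0.05, top_k: int | None = None, fallback_best: bool = True):
        self.alpha = alpha
        self.top_k = top_k
        self.fallback_best = fallback_best

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        scored = []
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0:
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            scored.append((col, float(r), float(p)))
        scored.sort(key=lambda t: (-abs(t[1]), str(t[0])))
        kept = [c for c, r, p in scored if p < self.alpha]
        if not kept:
            if not (self.fallback_best and scored):
                raise ValueError("no feature passes the screening")
            kept = [scored[0][0]]
        if self.top_k is not None:
            kept = kept[: self.top_k]
        self.retained_ = kept
        self.scores_ = pd.DataFrame(scored, columns=["feature", "r", "p_value"])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X[self.retained_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.retained_, dtype=object)
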