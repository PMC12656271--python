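"""Sample splitting, accuracy metrics and LAI map rendering.

The modeling/validation split sorts samples by measured LAI and assigns
every third rank (starting at rank 2) to validation, so both sets span the
observed LAI domain.  Accuracy is reported as

    R^2  = 1 - sum (x_i - y_i)^2 / sum (x_i - xbar)^2
    RMSE = sqrt( sum (x_i - y_i)^2 / n )
    MAE  = sum |x_i - y_i| / n

with x the measured and y the predicted LAI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import TextureIndexSpec, index_feature_frame
from .spectral import VI_NAMES, compute_vis, extract_roi_means
from .synthetic import BandStack
from .texture import texture_features_for_sample


@dataclass(frozen=True)
class SplitPlan:
    modeling_ids: tuple[int, ...]
    validation_ids: tuple[int, ...]
    fraction: float


@dataclass(frozen=True)
class EvalReport:
    r2: float
    rmse: float
    mae: float
    n: int
    split_label: str = ""


def sorted_split(lai_values, fraction: float = 1 / 3) -> SplitPlan:
    """Rank-systematic split spanning the LAI domain.

    Samples are ranked by LAI ascending (ties kept in stable input
    order); every floor(1/fraction)-th rank starting at rank 2 goes to
    validation until round(fraction * n) samples are selected.
    """
    lai = np.asarray(lai_values, dtype=float)
    n = len(lai)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    order = np.argsort(lai, kind="stable")
    step = int(np.floor(1.0 / fraction))
    quota = int(round(fraction * n))
    val_ranks = list(range(1, n, step))[:quota]
    validation = [int(order[r]) for r in val_ranks]
    val_set = set(validation)
    modeling = [int(i) for i in order if int(i) not in val_set]
    return SplitPlan(tuple(sorted(modeling)), tuple(sorted(validation)), fraction)


def metrics(observed, predicted, split_label: str = "") -> EvalReport:
    """R², RMSE and MAE of predictions against measured LAI."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    sq = float(np.sum((x - y) ** 2))
    rmse = float(np.sqrt(sq / len(x)))
    mae = float(np.mean(np.abs(x - y)))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant observed values: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - sq / ss_tot
    return EvalReport(r2=r2, rmse=rmse, mae=mae, n=len(x), split_label=split_label)


def evaluate_scenarios(model, X_val, y_val, X_ind, y_ind) -> tuple[EvalReport, EvalReport]:
    """Reports for the main validation split and the full independent scenario.

    ``model`` must have been trained on the main-scenario modeling split
    only; independent samples are used purely for prediction here.
    """
    rep_main = metrics(np.asarray(y_val, float), model.predict(X_val), "main_validation")
    rep_ind = metrics(np.asarray(y_ind, float), model.predict(X_ind), "independent")
    return rep_main, rep_ind


def predict_map(
    model,
    stack: BandStack,
    ti_specs: list[TextureIndexSpec] | None = None,
    window: int = 32,
    stride: int = 32,
    glcm_window: int = 4,
    offset=(1, 1),
    levels: int = 32,
) -> np.ndarray:
    """Coarse LAI raster: per tile, recompute the model's feature schema
    (band means → VIs, GLCM texture features, texture indices) and predict.
    """
    h, w = stack.shape
    if window > min(h, w):
        raise ValueError("stack smaller than map window")
    ti_specs = ti_specs or []
    schema = list(getattr(model, "feature_names_in_", []))
    ny = (h - window) // stride + 1
    nx = (w - window) // stride + 1
    out = np.full((ny, nx), np.nan)
    rows, pos = [], []
    for iy in range(ny):
        for ix in range(nx):
            y0, x0 = iy * stride, ix * stride
            tile = BandStack(
                {b: a[y0 : y0 + window, x0 : x0 + window] for b, a in stack.bands.items()}
            )
            means = extract_roi_means(tile, 0.0)
            feats = dict(zip(VI_NAMES, (compute_vis(means)[v] for v in VI_NAMES)))
            feats.update(
                texture_features_for_sample(
                    tile, 0.0, window=glcm_window, offset=offset, levels=levels
                )
            )
            rows.append(feats)
            pos.append((iy, ix))
    tf_table = pd.DataFrame(rows)
    if ti_specs:
        tf_table = pd.concat([tf_table, index_feature_frame(ti_specs, tf_table)], axis=1)
    missing = [c for c in schema if c not in tf_table.columns]
    if missing:
        raise ValueError(f"model features unavailable at tile scale: {missing}")
    preds = model.predict(tf_table[schema])
    for (iy, ix), v in zip(pos, preds):
        out[iy, ix] = v
    return out
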