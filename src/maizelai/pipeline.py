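"""End-to-end orchestration: simulate -> features -> select -> train ->
evaluate -> map, plus the 3 feature-set x 3 model-pair comparison grid."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluation import EvalReport, metrics, predict_map, sorted_split
from .indices import (
    RankedIndex, enumerate_candidates, index_feature_frame, select_top_indices,
)
from .io import ensure_dir, write_bandstack_tiff, write_lai_map_tiff, write_records_csv
from .models import StackedRegressor
from .selection import screen_features
from .spectral import MODEL_VI_NAMES, VI_NAMES, compute_vis, extract_roi_means
from .synthetic import (
    BAND_NAMES, generate_experiment, generate_independent_scenario,
)
from .texture import TF_NAMES, texture_features_for_sample

logger = logging.getLogger("maizelai")

META_COLUMNS = ("plot_id", "density", "nitrogen", "replicate", "date", "scenario", "lai_true")
FEATURE_SETS = ("vis", "vis+tfs", "vis+tfs+tis")
PAIRS = ("plsr+svm", "plsr+rf", "plsr+gbdt")


def build_feature_table(records, stacks, texture_cfg=None) -> pd.DataFrame:
    """One row per sample: metadata, band means, 11 VIs and 40 TFs."""
    from .config import TextureConfig

    tc = texture_cfg or TextureConfig()
    cols = list(META_COLUMNS) + list(BAND_NAMES) + list(VI_NAMES) + list(TF_NAMES)
    if not records:
        return pd.DataFrame(columns=cols)
    rows = []
    for rec in records:
        stack = stacks[(rec.plot_id, rec.date_index)]
        means = extract_roi_means(stack, tc.inner_buffer_frac)
        row = {
            "plot_id": rec.plot_id, "density": rec.density_label,
            "nitrogen": rec.nitrogen_label, "replicate": rec.replicate,
            "date": rec.date_index, "scenario": rec.scenario, "lai_true": rec.lai_true,
        }
        row.update(means)
        row.update(compute_vis(means))
        row.update(
            texture_features_for_sample(
                stack, tc.inner_buffer_frac, window=tc.window,
                offset=tc.offset, levels=tc.levels, mode=tc.mode,
            )
        )
        rows.append(row)
    return pd.DataFrame(rows)[cols]


@dataclass
class RunData:
    """Everything the training/evaluation stages need, stage by stage."""

    config: PipelineConfig
    main_records: list
    main_stacks: dict
    ind_records: list
    ind_stacks: dict
    main_table: pd.DataFrame
    ind_table: pd.DataFrame
    split: object
    screening_report: pd.DataFrame
    retained: dict[str, list[str]]
    ranked_tis: list[RankedIndex]
    feature_sets: dict[str, list[str]] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def prepare_run(config: PipelineConfig, include_independent: bool = True) -> RunData:
    """Run the deterministic data stages: simulate, features, split, select."""
    t0 = time.perf_counter()
    timings = {}
    design, canopy = config.synthetic.design, config.synthetic.canopy
    main_records, main_stacks = generate_experiment(design, canopy)
    if include_independent:
        ind_records, ind_stacks = generate_independent_scenario(design, canopy)
    else:
        ind_records, ind_stacks = [], {}
    timings["simulate"] = time.perf_counter() - t0
    logger.info("simulated %d main + %d independent samples",
                len(main_records), len(ind_records))

    t0 = time.perf_counter()
    main_table = build_feature_table(main_records, main_stacks, config.texture)
    ind_table = build_feature_table(ind_records, ind_stacks, config.texture)
    timings["features"] = time.perf_counter() - t0
    logger.info("extracted %d VI + %d TF feature columns", len(VI_NAMES), len(TF_NAMES))

    t0 = time.perf_counter()
    split = sorted_split(main_table["lai_true"].to_numpy(), config.evaluation.fraction)
    modeling = main_table.iloc[list(split.modeling_ids)]
    y_mod = modeling["lai_true"].to_numpy()
    report, retained = screen_features(
        modeling, y_mod, alpha=config.selection.alpha,
        feature_groups={"VI": list(MODEL_VI_NAMES), "TF": list(TF_NAMES)},
        top_k={"TF": config.selection.tf_k},
    )
    candidates = enumerate_candidates(retained["TF"])
    ranked = select_top_indices(
        candidates, modeling[retained["TF"]], y_mod,
        k=config.selection.ti_k, alpha=config.selection.alpha,
    )
    ti_specs = [r.spec for r in ranked]
    main_full = pd.concat(
        [main_table, index_feature_frame(ti_specs, main_table[list(TF_NAMES)])], axis=1
    )
    ind_full = pd.concat(
        [ind_table, index_feature_frame(ti_specs, ind_table[list(TF_NAMES)])], axis=1
    )
    timings["select"] = time.perf_counter() - t0

    ti_names = [r.spec.name for r in ranked]
    feature_sets = {
        "vis": list(retained["VI"]),
        "vis+tfs": list(retained["VI"]) + list(retained["TF"]),
        "vis+tfs+tis": list(retained["VI"]) + list(retained["TF"]) + ti_names,
    }
    return RunData(
        config=config, main_records=main_records, main_stacks=main_stacks,
        ind_records=ind_records, ind_stacks=ind_stacks,
        main_table=main_full, ind_table=ind_full, split=split,
        screening_report=report, retained=retained, ranked_tis=ranked,
        feature_sets=feature_sets, timings=timings,
    )


def fit_and_evaluate(run: RunData, pair: str | None = None, feature_set: str = "vis+tfs+tis"):
    """Fit one stack on the modeling split, report train/validation/independent."""
    cfg = run.config
    pair = pair or cfg.model.pair
    ml = pair.partition("+")[2]
    cols = run.feature_sets[feature_set]
    mod = run.main_table.iloc[list(run.split.modeling_ids)]
    val = run.main_table.iloc[list(run.split.validation_ids)]
    model = StackedRegressor(
        ml=ml, grids=cfg.model.grids, meta_k=cfg.model.meta_k,
        inner_cv=cfg.model.inner_cv, random_state=cfg.seed,
    )
    model.fit(mod[cols], mod["lai_true"].to_numpy())
    reports = {
        "train": metrics(mod["lai_true"], model.predict(mod[cols]), "modeling"),
        "validation": metrics(val["lai_true"], model.predict(val[cols]), "validation"),
    }
    if len(run.ind_table):
        reports["independent"] = metrics(
            run.ind_table["lai_true"], model.predict(run.ind_table[cols]), "independent"
        )
    return model, reports


def compare_feature_sets(config: PipelineConfig, run: RunData | None = None) -> pd.DataFrame:
    """The 3 x 3 comparison: feature sets x model pairs on identical splits."""
    run = run or prepare_run(config)
    split_hash = hash((run.split.modeling_ids, run.split.validation_ids)) & 0xFFFFFFFF
    rows = []
    for pair in PAIRS:
        for fs in FEATURE_SETS:
            _, reports = fit_and_evaluate(run, pair=pair, feature_set=fs)
            rows.append({
                "pair": pair, "feature_set": fs,
                "r2_train": reports["train"].r2, "rmse_train": reports["train"].rmse,
                "mae_train": reports["train"].mae,
                "r2_val": reports["validation"].r2, "rmse_val": reports["validation"].rmse,
                "mae_val": reports["validation"].mae,
                "n_train": reports["train"].n, "n_val": reports["validation"].n,
                "split_hash": split_hash, "seed": config.seed,
            })
    return pd.DataFrame(rows)


def _report_dict(rep: EvalReport) -> dict:
    return {"r2": rep.r2, "rmse": rep.rmse, "mae": rep.mae, "n": rep.n,
            "split_label": rep.split_label}


def run_pipeline(config: PipelineConfig, outdir, write_stacks: bool = False) -> dict:
    """Execute every stage and write features, screening, model summary,
    reports and the LAI map into ``outdir``.  Returns the report dict."""
    out = ensure_dir(outdir)
    t_start = time.perf_counter()
    run = prepare_run(config)
    cfg_stamp = {"config_hash": config.hash, "seed": config.seed}

    write_records_csv(run.main_records + run.ind_records, out / "samples.csv")
    run.main_table.to_csv(out / "features_main.csv", index=False)
    run.ind_table.to_csv(out / "features_independent.csv", index=False)
    run.screening_report.to_csv(out / "screening.csv", index=False)
    pd.DataFrame(
        [{"index_type": r.spec.index_type,
          "components": ";".join(r.spec.components),
          "r": r.r, "p": r.p_value, "selected": True} for r in run.ranked_tis]
    ).to_csv(out / "texture_indices.csv", index=False)
    if write_stacks:
        stack_dir = ensure_dir(out / "stacks")
        for (pid, date), stack in run.main_stacks.items():
            write_bandstack_tiff(stack, stack_dir / f"{pid}_d{date}.tif")

    t0 = time.perf_counter()
    model, reports = fit_and_evaluate(run)
    run.timings["train"] = time.perf_counter() - t0

    # LAI map of a peak-season high-density plot
    t0 = time.perf_counter()
    map_date = min(4, config.synthetic.design.dates)
    map_key = next(
        k for k in run.main_stacks if k[1] == map_date
    )
    ti_specs = [r.spec for r in run.ranked_tis]
    ev = config.evaluation
    lai_map = predict_map(
        model, run.main_stacks[map_key], ti_specs,
        window=ev.map_window, stride=ev.map_stride,
        glcm_window=config.texture.window, offset=config.texture.offset,
        levels=config.texture.levels,
    )
    write_lai_map_tiff(lai_map, out / "lai_map.tif")
    run.timings["map"] = time.perf_counter() - t0
    run.timings["total"] = time.perf_counter() - t_start

    if len(run.main_records) < 30:
        logger.warning("degraded-n run: only %d samples", len(run.main_records))

    report = {
        **cfg_stamp,
        "n_samples": len(run.main_records),
        "n_plots": len({r.plot_id for r in run.main_records}),
        "feature_sets": run.feature_sets,
        "tuned_params": {k: _jsonable(v) for k, v in model.tuned_params_.items()},
        "meta_coefficients": list(map(float, model.meta_coefficients_)),
        "reports": {k: _report_dict(v) for k, v in reports.items()},
        "timings": {k: round(v, 3) for k, v in run.timings.items()},
        "map_plot": {"plot_id": map_key[0], "date": map_key[1]},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "config.yaml", "w") as fh:
        fh.write(config.to_yaml())
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
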