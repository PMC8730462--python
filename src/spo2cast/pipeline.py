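"""End-to-end reproducible pipeline: simulate -> preprocess -> train ->
predict -> evaluate.

A run is driven by a single config mapping (typically loaded from YAML)
and a root seed; per-stage seeds are derived from the root so one number
reproduces the whole run. Every run directory gets a manifest recording
the resolved config, derived seeds and package version, plus per-stage
outputs: cohort and labels CSVs, processed-series CSV, exclusion report,
model archive, predictions CSV, and metrics JSON/CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import (
    aggregate_confusion,
    make_stay_prediction,
    sensitivity_subgroup_test,
    stay_metrics,
    summarize_cohort,
    ventilation_chisq,
)
from .forecaster import (
    LSTMForecaster,
    PersistenceForecaster,
    cross_validate,
    save_model,
)
from .io import read_cohort_csv
from .preprocess import (
    MIN_POINTS,
    apply_exclusions,
    build_supervised,
    concat_training,
    prepare_series,
    regularize_series,
)
from .series import RawStaySeries
from .simulate import SyntheticCohortConfig, generate_cohort, write_cohort_csv

__all__ = ["run_pipeline", "derive_stage_seeds", "PipelineError"]

logger = logging.getLogger("spo2cast")

_STAGES = ("simulate", "split", "forecaster", "cv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_stage_seeds(root_seed: int) -> dict:
    """Split one root seed into independent per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(int(root_seed)).generate_state(len(_STAGES))
    return {name: int(s % 2**31) for name, s in zip(_STAGES, state)}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _metrics_row(m) -> dict:
    tp, fp, tn, fn = m.counts
    return {
        "stay_id": m.stay_id,
        "cohort_label": m.cohort_label,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "ppv": m.ppv,
        "mse": m.mse,
        "pearson_r": m.pearson_r,
        "n_true_events": m.n_true_events,
    }


def _pooled_dict(agg) -> dict:
    tp, fp, tn, fn = agg.counts
    return {
        "counts": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        "false_positive_rate": agg.false_positive_rate,
        "false_negative_rate": agg.false_negative_rate,
        "sensitivity": agg.sensitivity,
        "specificity": agg.specificity,
        "ppv": agg.ppv,
        "accuracy": agg.accuracy,
    }


def evaluate_cohort(series_list, predictions, lags: int):
    """Per-stay metrics + pooled confusion for aligned stay forecasts."""
    per_stay = []
    for series, p_pred in zip(series_list, predictions):
        if p_pred.size == 0:
            continue
        per_stay.append(stay_metrics(make_stay_prediction(series, p_pred, lags=lags)))
    if not per_stay:
        raise ValueError("no stay produced a non-empty prediction")
    return per_stay, aggregate_confusion(per_stay)


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the configured stages and write all artifacts to ``out_dir``.

    Config keys (all optional unless noted): ``seed``; ``horizon_minutes``
    (5 or 30); ``lags``; ``train_fraction`` (stay-level train/test split,
    default 0.5); ``simulate`` (SyntheticCohortConfig fields) or
    ``input`` (path to a cohort CSV — exactly one of the two);
    ``cv`` ({"enabled": bool, "folds": int, plus LSTMForecaster overrides});
    ``forecaster`` (LSTMForecaster fields); ``min_points``;
    ``smooth_window``. Returns a results dict mirroring the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(dict(config), out, seed)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: dict, out: Path, seed: int | None) -> dict:
    root_seed = int(seed if seed is not None else config.get("seed", 0))
    seeds = derive_stage_seeds(root_seed)
    horizon = float(config.get("horizon_minutes", 5))
    lags = int(config.get("lags", 2))
    interval = float(config.get("sampling_interval_minutes", 5))
    min_points = int(config.get("min_points", MIN_POINTS))
    window = int(config.get("smooth_window", 5))
    train_fraction = float(config.get("train_fraction", 0.5))
    results: dict = {"seed": root_seed, "stage_seeds": seeds}

    # --- stage: cohort ----------------------------------------------------
    stage = "simulate"
    try:
        if "simulate" in config:
            sim_cfg = SyntheticCohortConfig(
                **{**config["simulate"], "seed": seeds["simulate"]}
            )
            cohort = generate_cohort(sim_cfg)
            write_cohort_csv(cohort, out / "cohort.csv")
            pd.DataFrame(
                {"stay_id": [s.stay_id for s in cohort],
                 "cohort_label": [s.cohort_label for s in cohort]}
            ).to_csv(out / "labels.csv", index=False)
            results["simulate"] = {"n_stays": len(cohort),
                                   "config": dataclasses.asdict(sim_cfg)}
            logger.info("simulate: generated %d stays", len(cohort))
        elif "input" in config:
            cohort = read_cohort_csv(config["input"])
            labels_path = Path(config["input"]).with_name("labels.csv")
            if labels_path.exists():
                labels = pd.read_csv(labels_path, dtype=str)
                label_map = dict(zip(labels["stay_id"], labels["cohort_label"]))
                for s in cohort:
                    s.cohort_label = label_map.get(s.stay_id, s.cohort_label)
            logger.info("load: read %d stays from %s", len(cohort), config["input"])
        else:
            raise ValueError("config must provide either 'simulate' or 'input'")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: preprocess ------------------------------------------------
    stage = "preprocess"
    try:
        blank = [s for s in cohort if s.is_blank]
        regular = [regularize_series(s, interval) for s in cohort if not s.is_blank]
        kept, dropped = apply_exclusions(regular, min_points=min_points)
        dropped = [(s, "blank") for s in blank] + dropped
        pd.DataFrame(
            {"stay_id": [s.stay_id for s, _ in dropped],
             "reason": [r for _, r in dropped]}
        ).to_csv(out / "exclusions.csv", index=False)
        series = [
            prepare_series(s, horizon_minutes=horizon, interval_minutes=interval,
                           window=window)
            for s in kept
        ]
        proc = pd.concat(
            [pd.DataFrame({"stay_id": ts.stay_id, "time_min": ts.times_minutes,
                           "p_smoothed": ts.p_values}) for ts in series],
            ignore_index=True,
        ) if series else pd.DataFrame(columns=["stay_id", "time_min", "p_smoothed"])
        proc.to_csv(out / "processed.csv", index=False)
        results["preprocess"] = {
            "stays_in": len(cohort), "kept": len(kept), "dropped": len(dropped),
            "reasons": {r: sum(1 for _, rr in dropped if rr == r)
                        for r in {"blank", "too_short"}},
        }
        logger.info("preprocess: kept %d / dropped %d of %d stays",
                    len(kept), len(dropped), len(cohort))
        if not series:
            raise ValueError("no stays survived exclusion")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: split + supervised ----------------------------------------
    stage = "split"
    try:
        rng = np.random.default_rng(seeds["split"])
        order = rng.permutation(len(series))
        n_train = max(1, int(round(train_fraction * len(series))))
        if len(series) > 1:
            n_train = min(n_train, len(series) - 1)
        train_series = [series[i] for i in order[:n_train]]
        test_series = [series[i] for i in order[n_train:]] or train_series
        train_sets = [d for d in (build_supervised(ts, lags=lags) for ts in train_series)
                      if d.n_rows > 0]
        if not train_sets:
            raise ValueError("training stays are all too short for the lag count")
        train_data = concat_training(train_sets)
        results["split"] = {"n_train_stays": len(train_series),
                            "n_test_stays": len(test_series),
                            "n_train_rows": train_data.n_rows}
        logger.info("split: %d train stays (%d rows), %d test stays",
                    len(train_series), train_data.n_rows, len(test_series))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    fc_cfg = dict(config.get("forecaster", {}))
    fc_cfg.setdefault("lags", lags)
    fc_cfg.setdefault("horizon_minutes", horizon)
    fc_cfg["seed"] = seeds["forecaster"]

    # --- stage: optional cross-validation ----------------------------------
    cv_cfg = dict(config.get("cv", {}))
    if cv_cfg.pop("enabled", False):
        stage = "cv"
        try:
            folds = int(cv_cfg.pop("folds", 3))
            cv_overrides = {k: v for k, v in fc_cfg.items()
                            if k not in ("architecture", "learning_rate", "seed")}
            cv_overrides.update(cv_cfg)
            cv_res = cross_validate(train_data, folds=folds, seed=seeds["cv"],
                                    **cv_overrides)
            fc_cfg["architecture"], fc_cfg["learning_rate"] = cv_res.selected
            _write_json(out / "cv.json", {
                "grid": [list(g) for g in cv_res.grid],
                "fold_mse": cv_res.fold_mse,
                "mean_mse": cv_res.mean_mse,
                "selected": list(cv_res.selected),
            })
            results["cv"] = {"selected": cv_res.selected}
            logger.info("cv: selected %s", cv_res.selected)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # --- stage: train -------------------------------------------------------
    stage = "train"
    try:
        est = LSTMForecaster(**fc_cfg)
        est.fit(train_data.X, train_data.Y)
        save_model(est, out / "model.npz")
        results["train"] = {"best_epoch": est.best_epoch_,
                            "val_loss": est.history_["val_loss"][est.best_epoch_],
                            "widths": list(est.lstm_widths_)}
        logger.info("train: best epoch %d (val MSE %.3g)",
                    est.best_epoch_, results["train"]["val_loss"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: predict -----------------------------------------------------
    stage = "predict"
    try:
        preds = [est.predict_series(ts) for ts in test_series]
        rows = []
        for ts, pp in zip(test_series, preds):
            if pp.size == 0:
                continue
            rows.append(pd.DataFrame({
                "stay_id": ts.stay_id,
                "time_min": ts.times_minutes[lags:],
                "p_true": ts.p_values[lags:],
                "p_pred": pp,
            }))
        pd.concat(rows, ignore_index=True).to_csv(out / "predictions.csv", index=False)
        logger.info("predict: %d test stays forecast", len(rows))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: evaluate ----------------------------------------------------
    stage = "evaluate"
    try:
        per_stay, pooled = evaluate_cohort(test_series, preds, lags=lags)
        pd.DataFrame([_metrics_row(m) for m in per_stay]).to_csv(
            out / "stay_metrics.csv", index=False)
        baseline = PersistenceForecaster()
        base_preds = [baseline.predict_series(ts, lags=lags) for ts in test_series]
        _, base_pooled = evaluate_cohort(test_series, base_preds, lags=lags)
        reports = {
            "pooled": _pooled_dict(pooled),
            "persistence_pooled": _pooled_dict(base_pooled),
            "summary": summarize_cohort(per_stay),
            "sensitivity_subgroups": sensitivity_subgroup_test(per_stay),
        }
        labels = sorted({m.cohort_label for m in per_stay})
        if len(labels) == 2:
            table = np.zeros((2, 2))
            for m in per_stay:
                i = labels.index(m.cohort_label)
                tp, fp, tn, fn = m.counts
                table[i, 0] += tp + fn          # hypoxemic timepoints
                table[i, 1] += tn + fp          # non-hypoxemic timepoints
            reports["ventilation_chisq"] = {"labels": labels,
                                            "table": table.tolist(),
                                            **ventilation_chisq(table)}
        _write_json(out / "metrics.json", reports)
        results["evaluate"] = reports
        logger.info("evaluate: pooled sensitivity %s, PPV %s",
                    reports["pooled"]["sensitivity"], reports["pooled"]["ppv"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest = {"config": config, "seed": root_seed, "stage_seeds": seeds,
                "version": __version__}
    _write_json(out / "manifest.json", manifest)
    return results
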