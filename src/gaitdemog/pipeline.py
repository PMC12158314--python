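"""End-to-end orchestration: simulate -> extract -> select -> train -> evaluate.

Every stage's effective settings are echoed to a JSON-lines run log, every
artifact directory is stamped with the configuration hash and seed, and all
artifacts are plain CSV/JSON so any stage can be rerun or inspected in
isolation.  Rerunning with the same configuration and seed reproduces every
artifact bit-for-bit (run logs carry wall-clock timings and are excluded
from that guarantee).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import features as ft
from . import models as md
from . import preprocess as pp
from . import simulate as sim
from .config import RunConfig

log = logging.getLogger("gaitdemog")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _log_stage(stage: str, elapsed: float, **params) -> None:
    log.info(json.dumps({"stage": stage, "elapsed_s": round(elapsed, 3), **params},
                        default=_json_default))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def simulate_stage(config: RunConfig, out_dir: Path) -> list:
    t0 = time.perf_counter()
    kwargs = dict(
        n_subjects=config.simulate.n_subjects,
        sex_ratio=config.simulate.sex_ratio,
        recording_duration=config.simulate.recording_duration,
        sampling_rate=config.simulate.sampling_rate,
        seed=config.seed,
    )
    if config.simulate.age_distribution is not None:
        kwargs["age_distribution"] = tuple(
            (tuple(b), w) for b, w in config.simulate.age_distribution
        )
    cohort = sim.generate_cohort(sim.CohortConfig(**kwargs))
    sim.cohort_metadata(cohort).to_csv(out_dir / "metadata.csv", index=False)
    _log_stage("simulate", time.perf_counter() - t0, **{k: v for k, v in kwargs.items()})
    return cohort


def extract_stage(config: RunConfig, cohort: list, out_dir: Path) -> pd.DataFrame:
    t0 = time.perf_counter()
    psettings = pp.PreprocessSettings(
        window_seconds=config.preprocess.window_seconds,
        overlap=config.preprocess.overlap,
        denoise=config.preprocess.denoise,
        denoise_first=config.preprocess.denoise_first,
        wavelet=pp.WaveletSettings(
            family=config.preprocess.wavelet.family,
            level=config.preprocess.wavelet.level,
            threshold=config.preprocess.wavelet.threshold,
        ),
    )
    fsettings = ft.FeatureSettings(
        peak_min_separation_s=config.features.peak_min_separation_s,
        welch_nperseg=config.features.welch_nperseg,
        welch_overlap=config.features.welch_overlap,
    )
    windows = []
    for rec, _ in cohort:
        windows.extend(pp.preprocess_recording(rec, psettings))
    table = ft.extract_table(windows, fsettings)
    table.to_csv(out_dir / "features.csv", index=False, float_format="%.12g")
    _log_stage("extract", time.perf_counter() - t0, n_windows=len(table),
               n_features=len(ft.feature_names(table)))
    return table


def select_stage(config: RunConfig, train: pd.DataFrame, out_dir: Path) -> dict[str, list[str]]:
    selected = {}
    for task in ("sex", "age"):
        t0 = time.perf_counter()
        names = md.rfe_select(train, task, n_keep=config.select.n_keep,
                              seed=config.seed, step=config.select.step)
        (out_dir / f"selected_{task}.txt").write_text("\n".join(names) + "\n")
        selected[task] = names
        _log_stage("select", time.perf_counter() - t0, task=task,
                   n_keep=config.select.n_keep)
    return selected


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages; returns a dict of reports and artifact paths."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(config), "seed": config.seed,
             "config": config.model_dump()}
    _write_json(out / "run_manifest.json", stamp)

    cohort = simulate_stage(config, out)
    table = extract_stage(config, cohort, out)
    train, test = md.split_dataset(table, config.split.train_fraction,
                                   by_subject=config.split.by_subject,
                                   seed=config.seed)
    selected = select_stage(config, train, out)

    reports: dict = {"config_hash": stamp["config_hash"], "seed": config.seed}

    # --- sex classification -------------------------------------------------
    t0 = time.perf_counter()
    y_test = md.encode_sex(test["sex"])
    sex_reports = {}
    for kind in config.models.classifiers:
        predictor = md.train_predictor(
            train, md.ModelConfig(kind, "sex", seed=config.seed),
            columns=selected["sex"])
        labels, scores = md.predict(predictor, test)
        sex_reports[kind] = ev.classification_metrics(y_test, labels, scores).to_dict()
    if config.models.stacking:
        stack = md.train_stacking(train, columns=selected["sex"], seed=config.seed)
        labels, scores = md.predict(stack, test)
        sex_reports["stacking"] = ev.classification_metrics(y_test, labels, scores).to_dict()
        if config.evaluate.by_age_group:
            sex_reports["stacking_by_age_group"] = ev.metrics_by_age_group(
                y_test, labels, test["age"].to_numpy(), task="sex", scores=scores
            ).to_dict()
        md.save_predictor(stack, out / "model_sex_stacking.joblib")
    _write_json(out / "report_sex.json",
                {"config_hash": stamp["config_hash"], "models": sex_reports})
    _log_stage("train_evaluate", time.perf_counter() - t0, task="sex",
               models=list(sex_reports))
    reports["sex"] = sex_reports

    # --- age regression -----------------------------------------------------
    t0 = time.perf_counter()
    y_age = test["age"].to_numpy(dtype=float)
    age_reports = {}
    best = None
    for kind in config.models.regressors:
        predictor = md.train_predictor(
            train, md.ModelConfig(kind, "age", seed=config.seed),
            columns=selected["age"])
        yhat = md.predict(predictor, test)
        rep = ev.regression_metrics(y_age, yhat)
        age_reports[kind] = rep.to_dict()
        if best is None or (rep.r2 or -np.inf) > best[2]:
            best = (kind, yhat, rep.r2 if rep.r2 is not None else -np.inf, predictor)
    if best is not None and config.evaluate.by_age_group:
        age_reports[f"{best[0]}_by_age_group"] = ev.metrics_by_age_group(
            y_age, best[1], test["age"].to_numpy(), task="age").to_dict()
    if best is not None:
        md.save_predictor(best[3], out / f"model_age_{best[0]}.joblib")
    _write_json(out / "report_age.json",
                {"config_hash": stamp["config_hash"], "models": age_reports})
    _log_stage("train_evaluate", time.perf_counter() - t0, task="age",
               models=list(age_reports))
    reports["age"] = age_reports

    if config.evaluate.by_position:
        t0 = time.perf_counter()
        pos_report = ev.compare_sensor_positions(
            table, "sex", seed=config.seed, columns=selected["sex"])
        _write_json(out / "report_position.json",
                    {"config_hash": stamp["config_hash"],
                     "sex": pos_report.to_dict()})
        _log_stage("compare_positions", time.perf_counter() - t0)
        reports["position"] = pos_report.to_dict()

    return reports
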