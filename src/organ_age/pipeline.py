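"""End-to-end experiment orchestration.

Runs generate -> preprocess -> train -> predict -> correct -> stratify ->
analyze as one reproducible experiment.  Every stage reads only the
previous stage's serialized outputs (cohort CSV, NIfTI pairs, prediction
CSVs, bias-model JSONs), so a run can be resumed from files, and rerunning
with the same configuration is bit-identical for the CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import pagstats, survival
from .age_model import AgeFitResults, AgeModel, healthy_exclusions_for, split_healthy
from .bias import BiasFit, fit_bias_model
from .config import (
    ORGANS_2D,
    ConfigurationError,
    ExperimentConfig,
    TrainConfig,
    stage_seed,
    validate_config,
)
from .preprocess import load_nifti, preprocess_image, qc_flag_volumes, save_nifti
from .synthetic import generate_cohort, render_seed, render_organ_image, write_cohort_csv


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def stage(self, name: str, t0: float, outputs: list[Path]) -> None:
        wall = time.time() - t0
        hashes = " ".join(f"{p.name}:{_file_hash(p)}" for p in outputs[:6])
        with self.path.open("a") as fh:
            fh.write(f"stage={name} wall_s={wall:.2f} {hashes}\n")


def _organ_dims(organ: str) -> tuple[int, int]:
    """(spatial dims, input channels) for an organ's rendering path."""
    return (2, 3) if organ in ORGANS_2D else (3, 1)


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Run the full experiment; returns the report directory.

    The directory contains cohort.csv, per-organ predictions and bias
    models, the PAG table with aging groups, the cross-organ correlation
    matrices, survival fits, KM/KDE figures and metrics.json.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("invalid configuration: " + "; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    metrics: dict = {"organs": {}, "outcomes": {}}

    try:
        cohort = _stage_synth(config, out, log)
        _stage_preprocess(config, cohort, out, log)
        predictions = _stage_train_predict(config, cohort, out, log, metrics)
        pag_table = _stage_correct(config, cohort, predictions, out, log, metrics)
        _stage_pagstats(config, pag_table, out, log, metrics)
        _stage_survival(config, cohort, pag_table, out, log, metrics)
    except Exception as exc:
        with (out / "run.log").open("a") as fh:
            fh.write(f"FAILED: {type(exc).__name__}: {exc}\n")
        raise

    t0 = time.time()
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=1, sort_keys=True))
    log.stage("metrics", t0, [metrics_path])
    return out


def _stage_synth(config: ExperimentConfig, out: Path, log: _RunLog) -> pd.DataFrame:
    t0 = time.time()
    cohort = generate_cohort(config.n_subjects, config.demographics,
                             config.factors, config.hazards,
                             seed=stage_seed(config.seed, "synth"))
    path = out / "cohort.csv"
    write_cohort_csv(cohort, path)
    raw_dir = out / "images_raw"
    raw_dir.mkdir(exist_ok=True)
    base = stage_seed(config.seed, "render")
    for organ in config.organs:
        for i, (_, row) in enumerate(cohort.iterrows()):
            img = render_organ_image(row, organ, config.phantom,
                                     seed=render_seed(base, i, organ))
            sid = row["subject_id"]
            save_nifti(img, raw_dir / f"{sid}_{organ}.nii.gz",
                       raw_dir / f"{sid}_{organ}_mask.nii.gz")
    log.stage("synth", t0, [path])
    return cohort


def _stage_preprocess(config: ExperimentConfig, cohort: pd.DataFrame,
                      out: Path, log: _RunLog) -> None:
    t0 = time.time()
    raw_dir, pre_dir = out / "images_raw", out / "images_pre"
    pre_dir.mkdir(exist_ok=True)
    qc_rows = []
    for organ in config.organs:
        dims, _ = _organ_dims(organ)
        target = config.phantom.fundus_shape if dims == 2 else config.target_grid
        volumes = []
        for sid in cohort["subject_id"]:
            img = load_nifti(raw_dir / f"{sid}_{organ}.nii.gz",
                             raw_dir / f"{sid}_{organ}_mask.nii.gz", organ)
            volumes.append(int(img.mask.sum()))
            pre = preprocess_image(img, margin=config.margin, target_shape=target)
            save_nifti(pre, pre_dir / f"{sid}_{organ}.nii.gz",
                       pre_dir / f"{sid}_{organ}_mask.nii.gz")
        if len(volumes) >= 3:
            flags = qc_flag_volumes(volumes, k=config.qc_k)
        else:
            flags = np.zeros(len(volumes), dtype=bool)
        for sid, vol, flag in zip(cohort["subject_id"], volumes, flags):
            qc_rows.append({"subject_id": sid, "organ": organ,
                            "mask_volume": vol, "qc_flag": int(flag)})
    qc_path = out / "qc_volumes.csv"
    pd.DataFrame(qc_rows).to_csv(qc_path, index=False)
    log.stage("preprocess", t0, [qc_path])


def _load_preprocessed(out: Path, cohort: pd.DataFrame, organ: str) -> list:
    pre_dir = out / "images_pre"
    return [load_nifti(pre_dir / f"{sid}_{organ}.nii.gz",
                       pre_dir / f"{sid}_{organ}_mask.nii.gz", organ)
            for sid in cohort["subject_id"]]


def _stage_train_predict(config: ExperimentConfig, cohort: pd.DataFrame,
                         out: Path, log: _RunLog, metrics: dict) -> pd.DataFrame:
    t0 = time.time()
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    ca = cohort["ca_at_imaging"].to_numpy()
    index = {sid: i for i, sid in enumerate(cohort["subject_id"])}
    frames = []
    for organ in config.organs:
        images = _load_preprocessed(out, cohort, organ)
        dims, channels = _organ_dims(organ)
        organ_seed = stage_seed(config.seed, f"train_{organ}")
        train_ids, test_ids = split_healthy(
            cohort, healthy_exclusions_for(organ),
            config.train.split_ratio, seed=organ_seed)
        tr = [index[s] for s in train_ids]
        te = [index[s] for s in test_ids]
        cfg = TrainConfig(**{**config.train.__dict__, "seed": organ_seed})
        model = AgeModel(dims=dims, in_channels=channels, config=cfg)
        results = model.fit([images[i] for i in tr], ca[tr])
        results.save(models_dir / f"{organ}.npz", models_dir / f"{organ}.json")
        test_eval = results.evaluate([images[i] for i in te], ca[te])
        baseline_mae = float(np.mean(np.abs(ca[te] - ca[tr].mean())))
        metrics["organs"][organ] = {
            "mae": round(test_eval["mae"], 6),
            "mae_sd": round(test_eval["mae_sd"], 6),
            "pearson_r": round(test_eval["pearson_r"], 6),
            "baseline_mae": round(baseline_mae, 6),
            "n_train": len(tr), "n_test": len(te),
        }
        frames.append(results.predict_frame(images, cohort["subject_id"], organ))
    predictions = pd.concat(frames, ignore_index=True)
    path = out / "predictions.csv"
    predictions.to_csv(path, index=False, float_format="%.6f")
    log.stage("train_predict", t0, [path])
    return predictions


def _disease_indicators(cohort: pd.DataFrame, organ: str) -> pd.DataFrame | None:
    """sex/existing/future covariate table for one organ's bias model."""
    ca = cohort["ca_at_imaging"].to_numpy()
    cov = pd.DataFrame({"sex": (cohort["sex"] == "male").astype(int).to_numpy()})
    exclusions = healthy_exclusions_for(organ)
    if exclusions:
        existing = np.zeros(len(cohort), dtype=int)
        future = np.zeros(len(cohort), dtype=int)
        for outcome in exclusions:
            col = f"age_{outcome}"
            if col not in cohort.columns:
                continue
            diag = cohort[col].to_numpy()
            has = pd.notna(diag)
            existing |= (has & (diag < ca)).astype(int)
            future |= (has & (diag >= ca)).astype(int)
        future &= 1 - existing
        if existing.any():
            cov["existing"] = existing
        if future.any():
            cov["future"] = future
    return cov


def _stage_correct(config: ExperimentConfig, cohort: pd.DataFrame,
                   predictions: pd.DataFrame, out: Path, log: _RunLog,
                   metrics: dict) -> pd.DataFrame:
    t0 = time.time()
    ca = cohort.set_index("subject_id")["ca_at_imaging"]
    bias_fits: dict[str, BiasFit] = {}
    outputs = []
    for organ in config.organs:
        sub = predictions[predictions["organ"] == organ]
        sub_ca = ca.loc[sub["subject_id"]].to_numpy()
        cov = _disease_indicators(cohort, organ)
        fit = fit_bias_model(sub["mu"].to_numpy() - sub_ca, sub_ca, cov)
        bias_fits[organ] = fit
        path = out / f"bias_{organ}.json"
        fit.to_json(path)
        outputs.append(path)
        metrics["organs"][organ]["bias_beta_age"] = round(fit.beta1_age, 6)
    pag_table = pagstats.pag_table(predictions, cohort, bias_fits)
    path = out / "pag_table.csv"
    pag_table.to_csv(path, index=False, float_format="%.6f")
    outputs.append(path)
    for organ in config.organs:
        theta = float(pag_table.loc[pag_table["organ"] == organ, "theta"].iloc[0])
        metrics["organs"][organ]["theta"] = round(theta, 6)
    log.stage("correct", t0, outputs)
    return pag_table


def _stage_pagstats(config: ExperimentConfig, pag_table: pd.DataFrame,
                    out: Path, log: _RunLog, metrics: dict) -> None:
    t0 = time.time()
    outputs = []
    wide = pag_table.pivot(index="subject_id", columns="organ",
                           values="pag_corrected")[list(config.organs)]
    if len(config.organs) >= 2:
        corr = pagstats.pairwise_pag_correlations(wide)
        for name in ("r", "p", "significant"):
            path = out / f"pag_corr_{name}.csv"
            corr[name].to_csv(path, float_format="%.6g")
            outputs.append(path)
        metrics["pag_correlations"] = {
            "n_complete": corr["n"], "n_tests": corr["n_tests"],
            "threshold": corr["threshold"],
        }
    if config.make_figures:
        _kde_figure(config, pag_table, out / "pag_kde.svg")
        outputs.append(out / "pag_kde.svg")
    log.stage("pagstats", t0, outputs)


def _kde_figure(config: ExperimentConfig, pag_table: pd.DataFrame,
                path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(config.organs),
                             figsize=(3.2 * len(config.organs), 2.8),
                             squeeze=False)
    for ax, organ in zip(axes[0], config.organs):
        pags = pag_table.loc[pag_table["organ"] == organ, "pag_corrected"]
        kde = pagstats.kde_summary(pags)
        ax.plot(kde["grid"], kde["density"])
        ax.axvspan(*kde["band"], alpha=0.15)
        ax.set_title(organ)
        ax.set_xlabel("corrected PAG (years)")
    axes[0][0].set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _stage_survival(config: ExperimentConfig, cohort: pd.DataFrame,
                    pag_table: pd.DataFrame, out: Path, log: _RunLog,
                    metrics: dict) -> None:
    t0 = time.time()
    outputs = []
    for outcome in config.survival_outcomes:
        hz = config.hazards.outcomes.get(outcome)
        organ = hz.source_organ if hz else config.organs[0]
        if organ not in config.organs:
            with (out / "run.log").open("a") as fh:
                fh.write(f"survival: skipped {outcome} (organ {organ} not modelled)\n")
            continue
        records = survival.build_records(cohort, outcome, pag_table, organ)
        doc: dict = {"outcome": outcome, "organ": organ,
                     "n": len(records), "n_events": int(records["event"].sum())}
        # each model variant may degenerate independently at desk scale
        # (few events, or a single aging group); record what it can
        try:
            group_fit = survival.cox_fit(records, ["group"])
            doc["group_hr"] = group_fit.hr["group"]
            doc["group_ci95"] = list(group_fit.ci95["group"])
            doc["group_p"] = group_fit.p["group"]
        except Exception as exc:
            doc["group_error"] = f"{type(exc).__name__}: {exc}"
        try:
            pag_fit = survival.cox_fit(records, ["pag"])
            doc["pag_hr"] = pag_fit.hr["pag"]
            doc["pag_hr_pct_per_year"] = survival.hr_per_year(pag_fit, "pag")
            doc["pag_ci95"] = list(pag_fit.ci95["pag"])
            doc["pag_p"] = pag_fit.p["pag"]
        except Exception as exc:
            doc["pag_error"] = f"{type(exc).__name__}: {exc}"
        try:
            full = survival.cox_fit(records, ["pag", "ca", "sex", "bmi"])
            reduced = survival.cox_fit(records, ["ca", "sex", "bmi"])
            doc["lrt_pag_beyond_clinical"] = survival.lr_test(full, reduced)
        except Exception as exc:
            doc["lrt_error"] = f"{type(exc).__name__}: {exc}"
        path = out / f"survival_{outcome}.json"
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        outputs.append(path)
        metrics["outcomes"][outcome] = {
            k: doc.get(k) for k in ("n", "n_events", "group_hr", "pag_hr",
                                    "pag_hr_pct_per_year")}
        km_frames = []
        for code, name in ((0, "decelerated"), (1, "typical"), (2, "accelerated")):
            sub = records[records["group"] == code]
            if len(sub) == 0:
                continue
            km = survival.km_estimate(sub, label=name)
            km["group"] = name
            km_frames.append(km)
        km_path = out / f"km_{outcome}.csv"
        pd.concat(km_frames, ignore_index=True).to_csv(
            km_path, index=False, float_format="%.6f")
        outputs.append(km_path)
        if config.make_figures:
            _km_figure(km_frames, outcome, out / f"km_{outcome}.svg")
    log.stage("survival", t0, outputs)


def _km_figure(km_frames: list[pd.DataFrame], outcome: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.0, 3.0))
    for km in km_frames:
        ax.step(km["age"], km["survival"], where="post",
                label=str(km["group"].iloc[0]))
    ax.set_xlabel("age (years)")
    ax.set_ylabel("event-free probability")
    ax.set_title(outcome)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
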