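"""Experiment orchestration: the maturity-classification and SSC-regression
pipelines, end to end, from phantom generation to metrics and saliency.

Every experiment is driven by one serializable :class:`ExperimentConfig`;
re-running an identical config reproduces all deterministic outputs.  The
classification experiment follows
simulate -> preprocess -> stratified split (x repeats) -> train 1D/3D ->
confusion matrices + accuracies + ANOVA across repeats -> saliency;
the regression experiment follows
simulate -> preprocess -> mean spectra -> PLS outlier screen -> SPXY split
-> train 1D regression -> R2/RMSE triad -> error-rate-gated saliency.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import anova_across_repeats, confusion_matrix, overall_accuracy, regression_metrics
from .models import ModelConfig, TrainedModel, build_resnet_1d, build_resnet_3d, train
from .preprocess import area_normalize, crop_bands, mean_spectrum, resize_cube, segment_fruit, sg_smooth
from .saliency import (
    ErrorRateRule,
    input_gradient,
    pixel_saliency,
    save_pixel_map_png,
    select_correct_classified,
    select_correct_regression,
    wavelength_contributions,
)
from .sampling import class_stratified_split, pls_outlier_removal, spxy_split
from .synthetic import PhantomConfig, simulate_samples

logger = logging.getLogger("berryspec")

__all__ = ["ExperimentConfig", "run_classification_experiment", "run_regression_experiment"]


@dataclass
class ExperimentConfig:
    """All knobs of one experiment, serializable to YAML.

    The generator block states the study conditions (class structure, SSC
    distributions, noise); the model blocks default to a desk-scale protocol
    (small cubes, shortened schedules) that preserves the full-scale
    architecture and optimizer settings.
    """

    # generator
    n_per_class: int = 50
    image_height: int = 24
    image_width: int = 24
    n_bands: int = 64
    wavelength_start: float = 380.0
    wavelength_end: float = 1030.0
    noise_sd: float = 0.01
    ssc_bump_amplitude: float = 0.004
    couple_ssc_to_class: bool = True
    # preprocessing
    crop_low: float = 441.0
    crop_high: float = 947.0
    sg_window: int = 11
    sg_polyorder: int = 3
    resize_rows: int | None = None  # None: keep the generated spatial dims
    resize_cols: int | None = None
    # classification splits
    n_val_per_class: int | None = None  # None: n_per_class // 6 (study ratio 34/204)
    n_test_per_class: int | None = None
    n_repeats: int = 5
    models: tuple[str, ...] = ("1d", "3d")
    epochs_1d: int = 300
    epochs_3d: int = 100
    # regression
    outlier_k: float = 3.0
    split_ratio: tuple[int, int, int] = (4, 1, 1)
    epochs_regression: int = 1500
    # saliency
    error_rate_thresholds: tuple[float, ...] = (0.05, 0.10)
    # misc
    batch_size: int = 32
    standardize_inputs: bool = True
    master_seed: int = 1

    def resolved_counts(self) -> tuple[int, int]:
        n_val = self.n_val_per_class if self.n_val_per_class is not None else max(1, self.n_per_class // 6)
        n_test = self.n_test_per_class if self.n_test_per_class is not None else max(1, self.n_per_class // 6)
        return n_val, n_test

    def phantom_template(self) -> PhantomConfig:
        return PhantomConfig(
            image_height=self.image_height,
            image_width=self.image_width,
            wavelength_start=self.wavelength_start,
            wavelength_end=self.wavelength_end,
            n_bands=self.n_bands,
            noise_sd=self.noise_sd,
            ssc_bump_amplitude=self.ssc_bump_amplitude,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("models", "split_ratio", "error_rate_thresholds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _fanout(master_seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31)]


def _prepare_samples(config: ExperimentConfig, need_cubes: bool, couple: bool | None = None):
    """Simulate phantoms and run the preprocessing chain.

    Returns (spectra (N, B), cubes (N, r, c, B) or None, labels, ssc,
    wavelengths).
    """
    t0 = time.time()
    couple = config.couple_ssc_to_class if couple is None else couple
    phantoms = simulate_samples(
        config.n_per_class, config.phantom_template(), config.master_seed, couple_ssc_to_class=couple
    )
    spectra, cubes, labels, ssc = [], [], [], []
    wavelengths = None
    for ph in phantoms:
        cropped = crop_bands(ph.cube, config.crop_low, config.crop_high)
        smoothed = sg_smooth(cropped, config.sg_window, config.sg_polyorder)
        mask = segment_fruit(smoothed)
        normalized = area_normalize(smoothed)
        spectra.append(mean_spectrum(normalized, mask).values)
        if need_cubes:
            rows = config.resize_rows or config.image_height
            cols = config.resize_cols or config.image_width
            cubes.append(resize_cube(normalized, rows, cols).values)
        labels.append(ph.maturity_label)
        ssc.append(ph.ssc)
        wavelengths = normalized.wavelengths
    logger.info("prepared %d samples in %.1fs", len(phantoms), time.time() - t0)
    X1d = np.asarray(spectra)
    X3d = np.asarray(cubes, dtype=np.float32) if need_cubes else None
    return X1d, X3d, np.asarray(labels), np.asarray(ssc), wavelengths


def _model_config(kind: str, config: ExperimentConfig, n_bands: int, seed: int, task: str) -> ModelConfig:
    if kind == "1d":
        return ModelConfig(
            input_kind="spectrum",
            task=task,
            n_bands=n_bands,
            epochs=config.epochs_regression if task == "regression" else config.epochs_1d,
            batch_size=config.batch_size,
            standardize_inputs=config.standardize_inputs,
            seed=seed,
        )
    rows = config.resize_rows or config.image_height
    cols = config.resize_cols or config.image_width
    return ModelConfig(
        input_kind="cube",
        task=task,
        n_bands=n_bands,
        spatial_dims=(rows, cols),
        epochs=config.epochs_3d,
        batch_size=config.batch_size,
        standardize_inputs=config.standardize_inputs,
        seed=seed,
    )


def _write_frame(frame: pd.DataFrame, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        frame.to_csv(out_dir / name, index=False)


def run_classification_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Full maturity-classification pipeline; returns the report bundle.

    The report holds per-repeat/model/set accuracies and confusion matrices,
    the repeat ANOVA comparing 1D vs 3D (when both are trained over >= 2
    repeats), pooled and per-class saliency profiles from the first repeat's
    test set, and (for the 3D model) pixel saliency maps.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_path / "config.yaml")
    need_cubes = "3d" in config.models
    X1d, X3d, labels, _, wavelengths = _prepare_samples(config, need_cubes)
    n_val, n_test = config.resolved_counts()
    seeds = _fanout(config.master_seed, 2 * config.n_repeats + 2)

    acc_rows = []
    confusions: dict[tuple[int, str, str], np.ndarray] = {}
    first_models: dict[str, TrainedModel] = {}
    splits = []
    for rep in range(config.n_repeats):
        split = class_stratified_split(labels, n_val, n_test, seed=seeds[rep], repeat_id=rep)
        splits.append(split)
        for kind in config.models:
            X = X1d if kind == "1d" else X3d
            mc = _model_config(kind, config, X1d.shape[1], seeds[config.n_repeats + rep], "classification")
            net = build_resnet_1d(mc) if kind == "1d" else build_resnet_3d(mc)
            t0 = time.time()
            tm = train(net, X[split.train], labels[split.train], X[split.validation], labels[split.validation], mc)
            logger.info("repeat %d %s model trained in %.1fs", rep, kind, time.time() - t0)
            if rep == 0:
                first_models[kind] = tm
            for set_name, idx in (("train", split.train), ("validation", split.validation), ("test", split.test)):
                cm = confusion_matrix(labels[idx], tm.predict(X[idx]), set_tag=set_name)
                confusions[(rep, kind, set_name)] = cm
                acc_rows.append(
                    {"repeat": rep, "model": kind, "set": set_name, "accuracy": overall_accuracy(cm)}
                )
    accuracy = pd.DataFrame(acc_rows)

    anova = None
    if len(config.models) >= 2 and config.n_repeats >= 2:
        pooled = accuracy.pivot_table(index=["repeat", "set"], columns="model", values="accuracy")
        per_set = {
            s: accuracy[accuracy["set"] == s].pivot(index="repeat", columns="model", values="accuracy")
            for s in ("train", "validation", "test")
        }
        anova = {"pooled": anova_across_repeats(pooled), "per_set": {s: anova_across_repeats(t) for s, t in per_set.items()}}

    sal: dict = {}
    split0 = splits[0]
    for kind, tm in first_models.items():
        X = X1d if kind == "1d" else X3d
        X_test, y_test = X[split0.test], labels[split0.test]
        correct = select_correct_classified(tm, X_test, y_test)
        if correct.size:
            grads = input_gradient(tm, X_test[correct], y_test[correct])
            profile = wavelength_contributions(grads, wavelengths)
            per_class = {}
            for cls in range(4):
                cls_sel = correct[y_test[correct] == cls]
                if cls_sel.size:
                    g = input_gradient(tm, X_test[cls_sel], y_test[cls_sel])
                    per_class[cls] = wavelength_contributions(g, wavelengths)
            sal[kind] = {"pooled": profile, "per_class": per_class}
            if out_path is not None:
                profile.to_csv(out_path / f"saliency_{kind}_pooled.csv")
        if kind == "3d":
            maps = [
                pixel_saliency(tm, X_test[i], sample_id=f"test_{i}") for i in range(min(2, X_test.shape[0]))
            ]
            sal.setdefault(kind, {})["pixel_maps"] = maps
            if out_path is not None:
                for i, pm in enumerate(maps):
                    save_pixel_map_png(pm, out_path / f"saliency_3d_pixel_{i}.png")

    _write_frame(accuracy, out_path, "accuracies.csv")
    if out_path is not None:
        cm_rows = []
        for (rep, kind, set_name), cm in confusions.items():
            frame = cm.to_frame()
            frame.insert(0, "repeat", rep)
            frame.insert(1, "model", kind)
            frame.insert(2, "set", set_name)
            cm_rows.append(frame.reset_index(names="true_class"))
        pd.concat(cm_rows).to_csv(out_path / "confusion_matrices.csv", index=False)
        if anova is not None:
            (out_path / "anova.json").write_text(json.dumps(anova, indent=2, default=float))
        split_rows = []
        for sp in splits:
            for set_name, idx in (("train", sp.train), ("validation", sp.validation), ("test", sp.test)):
                for i in idx:
                    split_rows.append({"sample_id": int(i), "set": set_name, "repeat_id": sp.repeat_id, "seed": sp.seed})
        _write_frame(pd.DataFrame(split_rows), out_path, "split_manifest.csv")

    return {
        "accuracy": accuracy,
        "confusions": confusions,
        "anova": anova,
        "saliency": sal,
        "models": first_models,
        "splits": splits,
        "wavelengths": wavelengths,
        "labels": labels,
        "X1d": X1d,
    }


def run_regression_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Full SSC-regression pipeline; returns the report bundle with the
    R2/RMSE triad, the outlier report, the SPXY split and the saliency
    profiles at each error-rate threshold."""
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_path / "config.yaml")
    X, _, labels, ssc, wavelengths = _prepare_samples(config, need_cubes=False)

    retained, flagged = pls_outlier_removal(X, ssc, k=config.outlier_k)
    logger.info("outlier screen removed %d of %d samples", flagged.size, X.shape[0])
    Xr, yr = X[retained], ssc[retained]

    ratio = np.asarray(config.split_ratio, dtype=float)
    n = Xr.shape[0]
    n_val = int(n * ratio[1] / ratio.sum())
    n_test = int(n * ratio[2] / ratio.sum())
    n_train = n - n_val - n_test
    split = spxy_split(Xr, yr, n_train, n_val, n_test)

    seeds = _fanout(config.master_seed, 3)
    mc = _model_config("1d", config, X.shape[1], seeds[0], "regression")
    net = build_resnet_1d(mc)
    t0 = time.time()
    tm = train(net, Xr[split.train], yr[split.train], Xr[split.validation], yr[split.validation], mc)
    logger.info("regression model trained in %.1fs", time.time() - t0)

    metrics = {}
    for set_name, idx in (("train", split.train), ("validation", split.validation), ("test", split.test)):
        metrics[set_name] = regression_metrics(yr[idx], tm.predict(Xr[idx]), set_tag=set_name)
    metrics_frame = pd.DataFrame(
        [{"set": s, "r2": m.r2, "rmse": m.rmse} for s, m in metrics.items()]
    )

    profiles = {}
    X_test, y_test = Xr[split.test], yr[split.test]
    for thr in config.error_rate_thresholds:
        rule = ErrorRateRule(thr)
        sel = select_correct_regression(tm, X_test, y_test, rule)
        if sel.size:
            grads = input_gradient(tm, X_test[sel])
            profiles[thr] = wavelength_contributions(grads, wavelengths)
            if out_path is not None:
                profiles[thr].to_csv(out_path / f"saliency_regression_{int(thr * 100)}pct.csv")

    _write_frame(metrics_frame, out_path, "regression_metrics.csv")
    if out_path is not None:
        pd.DataFrame({"flagged_index": flagged}).to_csv(out_path / "outlier_report.csv", index=False)

    return {
        "metrics": metrics,
        "metrics_frame": metrics_frame,
        "model": tm,
        "split": split,
        "retained": retained,
        "flagged": flagged,
        "profiles": profiles,
        "wavelengths": wavelengths,
        "X": Xr,
        "y": yr,
        "labels": labels[retained],
    }
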