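"""Config-driven orchestration of the three benchmark frameworks.

``tabular`` runs impute -> IQR capping -> ten-fold plan -> per-model
tuning -> pooled ten-fold predictions -> metric reports -> paired
Wilcoxon/McNemar significance matrices. ``cae`` and ``scae`` run image
preprocessing -> autoencoder training on the train partition -> feature
extraction -> in-train tuning -> hold-out evaluation -> the same metric
and test machinery.

One master seed fans out to per-stage seeds through a fixed counter
scheme (seed * 9973 + stage index, mod 2^31), so a single config + seed
reproduces byte-identical report CSVs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .autoencoder import LeakageAudit, TrainConfig, build_scae_features
from .classifiers import (CvResult, ModelSpec, grid_search_cv,
                          holdout_fit_predict, pooled_fold_predictions)
from .evaluation import MetricReport, metrics, round_display, sum_accuracy
from .preprocessing import ImputeStrategy, assign_folds, clip_outliers_iqr, impute
from .statcompare import significance_matrix
from .synthetic import (ImageSet, ImageSimSpec, MorphometricTable,
                        TabularSimSpec, generate_images, generate_tabular)

__all__ = [
    "ExperimentConfig",
    "FrameworkResult",
    "run_tabular_framework",
    "run_image_framework",
    "stage_seed",
]

_STAGES = ("synth", "folds", "tune", "fit", "autoencoder", "split")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (master * 9973 + index) mod 2^31."""
    return (master_seed * 9973 + _STAGES.index(stage)) % (2**31)


@dataclass
class ExperimentConfig:
    framework: str = "tabular"  # tabular | cae | scae
    models: tuple[str, ...] = ("mlp", "knn", "gnb", "rf", "svm", "kan")
    imputation: str = "mode"
    iqr_multiplier: float = 3.0
    scale_kind: str = "standard"  # standard | minmax | none
    n_folds: int = 10
    seed: int = 0
    out_dir: str | None = None
    # synthetic-data knobs (used when no dataset is supplied)
    tabular: TabularSimSpec | None = None
    images: ImageSimSpec | None = None
    # model knobs
    tuning_grids: dict | None = None  # family -> grid override
    kan_hidden_dims: tuple[int, ...] = (256, 128, 64, 32)
    kan_max_epochs: int = 200
    ae_train: TrainConfig | None = None

    def __post_init__(self) -> None:
        if self.framework not in ("tabular", "cae", "scae"):
            raise ValueError(f"unknown framework {self.framework!r}")

    def model_spec(self, family: str) -> ModelSpec:
        grid = None
        if self.tuning_grids and family in self.tuning_grids:
            grid = dict(self.tuning_grids[family])
        params: dict = {}
        if family == "kan":
            params = {"hidden_dims": self.kan_hidden_dims,
                      "max_epochs": self.kan_max_epochs}
        return ModelSpec(family, params, grid)


@dataclass
class FrameworkResult:
    reports: dict[str, MetricReport]
    predictions: dict[str, np.ndarray]
    truth: np.ndarray
    wilcoxon: dict
    mcnemar: dict
    accuracy_sum: float
    manifest: dict


def _config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]


def _report_rows(reports: dict[str, MetricReport]) -> list[str]:
    lines = ["model,accuracy,recall,specificity,precision,f1,mcc"]
    for name, rep in reports.items():
        r = rep.rounded()
        lines.append(
            f"{name},{r['accuracy']:.3f},{r['sensitivity']:.3f},"
            f"{r['specificity']:.3f},{r['precision']:.3f},"
            f"{r['f1']:.3f},{r['mcc']:.3f}"
        )
    return lines


def _matrix_rows(matrix: dict) -> list[str]:
    lines = ["model_a,model_b,statistic,p_value,significant,better_model"]
    for (a, b), res in matrix.items():
        lines.append(
            f"{a},{b},{res.statistic:.6g},{res.p_value:.6g},"
            f"{int(res.significant)},{res.better_model}"
        )
    return lines


def _write_artifacts(result: FrameworkResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.csv"), "w") as fh:
        fh.write("\n".join(_report_rows(result.reports)) + "\n")
    for name, matrix in (("wilcoxon", result.wilcoxon),
                         ("mcnemar", result.mcnemar)):
        with open(os.path.join(out_dir, f"{name}.csv"), "w") as fh:
            fh.write("\n".join(_matrix_rows(matrix)) + "\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def _finish(cfg, reports, predictions, truth, extra_manifest) -> FrameworkResult:
    names = list(reports)
    wil = significance_matrix(names, predictions, truth, "wilcoxon")
    mcn = significance_matrix(names, predictions, truth, "mcnemar")
    acc_sum = sum_accuracy(list(reports.values()))
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "framework": cfg.framework,
        "seed": cfg.seed,
        "models": list(cfg.models),
        "accuracy_sum": acc_sum,
        **extra_manifest,
    }
    result = FrameworkResult(reports, predictions, truth, wil, mcn,
                             acc_sum, manifest)
    if cfg.out_dir:
        _write_artifacts(result, cfg.out_dir)
    return result


def run_tabular_framework(
    cfg: ExperimentConfig, table: MorphometricTable | None = None
) -> FrameworkResult:
    """Pooled ten-fold benchmark on a (possibly synthetic) morphometric table."""
    if table is None:
        sim = cfg.tabular or TabularSimSpec(seed=stage_seed(cfg.seed, "synth"))
        table = generate_tabular(sim)
    try:
        folds = assign_folds(table.labels, cfg.n_folds,
                             seed=stage_seed(cfg.seed, "folds"))
        clean = impute(table, ImputeStrategy(cfg.imputation))
        clean = clip_outliers_iqr(clean, cfg.iqr_multiplier)
    except Exception as exc:
        raise RuntimeError(f"tabular preprocessing stage failed: {exc}") from exc

    reports: dict[str, MetricReport] = {}
    predictions: dict[str, np.ndarray] = {}
    for family in cfg.models:
        spec = cfg.model_spec(family)
        try:
            best, _ = grid_search_cv(spec, clean, folds, cfg.scale_kind,
                                     seed=stage_seed(cfg.seed, "tune"))
            cv = pooled_fold_predictions(spec, clean, folds, cfg.scale_kind,
                                         hyperparameters=best,
                                         seed=stage_seed(cfg.seed, "fit"))
        except Exception as exc:
            raise RuntimeError(f"model stage failed for {family}: {exc}") from exc
        reports[family] = metrics(cv.cm)
        predictions[family] = cv.predictions
    return _finish(cfg, reports, predictions, table.labels,
                   {"n_rows": table.n_rows, "imputation": cfg.imputation})


def run_image_framework(
    cfg: ExperimentConfig,
    stacked: bool | None = None,
    imageset: ImageSet | None = None,
) -> tuple[FrameworkResult, LeakageAudit]:
    """CAE/SCAE feature extraction plus hold-out benchmark.

    ``stacked`` defaults from the framework name; returns the result and
    the leakage audit recording which rows the autoencoders trained on.
    """
    if stacked is None:
        stacked = cfg.framework == "scae"
    if imageset is None:
        sim = cfg.images or ImageSimSpec(seed=stage_seed(cfg.seed, "synth"))
        imageset = generate_images(sim)
    audit = LeakageAudit()
    ae_cfg = cfg.ae_train or TrainConfig(seed=stage_seed(cfg.seed, "autoencoder"))
    try:
        cae_fm, scae_fm = build_scae_features(imageset, ae_cfg, audit=audit)
    except Exception as exc:
        raise RuntimeError(f"autoencoder stage failed: {exc}") from exc
    fm = scae_fm if stacked else cae_fm

    train_mask = fm.partition == "train"
    ids = np.arange(len(fm.labels))
    reports: dict[str, MetricReport] = {}
    predictions: dict[str, np.ndarray] = {}
    for family in cfg.models:
        spec = cfg.model_spec(family)
        try:
            pred, cm, _ = holdout_fit_predict(
                spec,
                fm.values[train_mask], fm.labels[train_mask],
                fm.values[~train_mask], fm.labels[~train_mask],
                tuning_folds=cfg.n_folds, scale_kind=cfg.scale_kind,
                seed=stage_seed(cfg.seed, "tune"),
                train_ids=ids[train_mask], test_ids=ids[~train_mask],
            )
        except Exception as exc:
            raise RuntimeError(f"model stage failed for {family}: {exc}") from exc
        reports[family] = metrics(cm)
        predictions[family] = pred
    result = _finish(cfg, reports, predictions, fm.labels[~train_mask],
                     {"feature_dim": int(fm.values.shape[1]),
                      "stacked": stacked,
                      "n_train": int(train_mask.sum()),
                      "n_test": int((~train_mask).sum())})
    return result, audit
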