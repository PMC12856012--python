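"""Tabular cleaning, the stratified ten-fold plan, and image normalization.

The tabular pipeline mirrors the study protocol: impute missing cells
(mean / median / mode / k-nearest-neighbours with k=5), cap outliers with
the IQR fence at multiplier 3, then scale inside each training fold
(standardization or min-max to [0, 1]). The fold plan reproduces the
study's printed per-fold female/male counts for the 62/50 dataset and
falls back to a round-robin class balance otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthetic import FEMALE, MALE, MorphometricTable

__all__ = [
    "ImputeStrategy",
    "IqrParams",
    "ScalerState",
    "FoldPlan",
    "TABLE1_FOLD_COUNTS",
    "impute",
    "clip_outliers_iqr",
    "fit_scaler",
    "apply_scaler",
    "assign_folds",
    "preprocess_image",
]

#: per-fold (female, male) counts of the study's ten-fold plan for 62 F / 50 M
TABLE1_FOLD_COUNTS = [
    (7, 5), (7, 5), (6, 5), (6, 5), (6, 5),
    (6, 5), (6, 5), (4, 7), (7, 4), (7, 4),
]


@dataclass(frozen=True)
class ImputeStrategy:
    kind: str = "mean"  # one of mean, median, mode, knn
    k: int = 5  # neighbour count, knn only

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "median", "mode", "knn"):
            raise ValueError(f"unknown imputation kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class IqrParams:
    """Per-feature quartiles and the derived capping boundaries."""

    multiplier: float
    q1: np.ndarray
    q3: np.ndarray

    @property
    def iqr(self) -> np.ndarray:
        return self.q3 - self.q1

    @property
    def lower(self) -> np.ndarray:
        return self.q1 - self.multiplier * self.iqr

    @property
    def upper(self) -> np.ndarray:
        return self.q3 + self.multiplier * self.iqr


@dataclass
class ScalerState:
    """Fitted per-feature scaling parameters (training data only).

    ``standard``: z = (x - u) / s with the population SD; constant features
    get scale 1 with a warning. ``minmax``: affine map of [min, max] onto
    the target range (default [0, 1]); applied to unseen data it may land
    outside the range (no clipping).
    """

    kind: str
    center: np.ndarray  # u (standard) or per-feature min (minmax)
    scale: np.ndarray  # s (standard) or max - min (minmax)
    feature_names: list[str]
    target_range: tuple[float, float] = (0.0, 1.0)


def _modal_value(col: np.ndarray) -> float:
    vals, counts = np.unique(col, return_counts=True)
    # smallest modal value on ties: np.unique returns sorted values
    return float(vals[np.argmax(counts)])


def impute(table: MorphometricTable, strategy: ImputeStrategy) -> MorphometricTable:
    """Fill every missing cell; observed cells are never altered."""
    out = table.copy()
    mask = out.missing_mask
    if not mask.any():
        out.missing_mask = np.zeros_like(mask)
        return out
    all_missing = mask.all(axis=0)
    if all_missing.any():
        name = out.feature_names[int(np.argmax(all_missing))]
        raise ValueError(f"feature {name!r} has no observed values to impute from")

    if strategy.kind == "knn":
        _impute_knn(out.values, mask, strategy.k)
    else:
        for j in range(out.n_features):
            col = out.values[:, j]
            obs = col[~mask[:, j]]
            if strategy.kind == "mean":
                fill = float(np.mean(obs))
            elif strategy.kind == "median":
                fill = float(np.median(obs))
            else:
                fill = _modal_value(obs)
            col[mask[:, j]] = fill
    out.missing_mask = np.zeros_like(mask)
    return out


def _impute_knn(values: np.ndarray, mask: np.ndarray, k: int) -> None:
    """Fill cells in place with the mean of the k nearest rows.

    Distance is plain Euclidean over the features observed in both rows;
    candidate donors must observe the target feature. Ties broken by row
    index; fewer than k donors -> use all; no commonly observed features
    -> the donor is skipped (falls back to column mean if none remain).
    """
    n, p = values.shape
    filled = values.copy()  # distances use the original observed cells only
    rows_with_missing = np.where(mask.any(axis=1))[0]
    for i in rows_with_missing:
        obs_i = ~mask[i]
        dists = np.full(n, np.inf)
        for r in range(n):
            if r == i:
                continue
            common = obs_i & ~mask[r]
            if not common.any():
                continue
            diff = filled[i, common] - filled[r, common]
            dists[r] = float(np.sqrt(np.sum(diff * diff)))
        for j in np.where(mask[i])[0]:
            donor_ok = np.isfinite(dists) & ~mask[:, j]
            donors = np.where(donor_ok)[0]
            if donors.size == 0:
                values[i, j] = float(np.nanmean(np.where(mask[:, j], np.nan,
                                                         filled[:, j])))
                continue
            order = donors[np.argsort(dists[donors], kind="stable")]
            chosen = order[: min(k, order.size)]
            values[i, j] = float(np.mean(filled[chosen, j]))


def fit_iqr(table: MorphometricTable, multiplier: float = 3.0) -> IqrParams:
    if table.missing_mask.any():
        raise ValueError("IQR capping requires a fully imputed table")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    q1 = np.quantile(table.values, 0.25, axis=0, method="linear")
    q3 = np.quantile(table.values, 0.75, axis=0, method="linear")
    return IqrParams(multiplier, q1, q3)


def clip_outliers_iqr(
    table: MorphometricTable, multiplier: float = 3.0
) -> MorphometricTable:
    """Cap values outside the IQR fence at the nearest boundary.

    Quartiles use linear interpolation between order statistics. The
    operation is idempotent: the capped table has the same quartiles'
    fences containing every value.
    """
    params = fit_iqr(table, multiplier)
    out = table.copy()
    out.values = np.clip(out.values, params.lower, params.upper)
    return out


def fit_scaler(train: MorphometricTable, kind: str = "standard") -> ScalerState:
    if kind not in ("standard", "minmax"):
        raise ValueError(f"unknown scaler kind {kind!r}")
    if train.missing_mask.any():
        raise ValueError("scaler must be fitted on a fully imputed table")
    x = train.values
    if kind == "standard":
        u = x.mean(axis=0)
        s = x.std(axis=0)  # population SD (divide by n)
        const = s == 0
        if const.any():
            names = [train.feature_names[j] for j in np.where(const)[0]]
            warnings.warn(
                f"constant feature(s) {names} under standardization; scale set to 1",
                stacklevel=2,
            )
            s = np.where(const, 1.0, s)
        return ScalerState("standard", u, s, list(train.feature_names))
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    span = np.where(span == 0, 1.0, span)
    return ScalerState("minmax", lo, span, list(train.feature_names))


def apply_scaler(state: ScalerState, table: MorphometricTable) -> MorphometricTable:
    if list(table.feature_names) != state.feature_names:
        raise ValueError("scaler fitted on a different feature set")
    out = table.copy()
    std = (out.values - state.center) / state.scale
    if state.kind == "standard":
        out.values = std
    else:
        lo, hi = state.target_range
        out.values = std * (hi - lo) + lo
    return out


@dataclass
class FoldPlan:
    """Partition of rows into folds with exact per-fold class counts."""

    n_folds: int
    assignments: np.ndarray  # per-row fold index in [0, n_folds)
    class_counts: list[dict[str, int]]  # per-fold {sex: count}

    def test_indices(self, fold: int) -> np.ndarray:
        return np.where(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.assignments != fold)[0]


def _round_robin_targets(
    counts: dict[str, int], n_folds: int
) -> list[dict[str, int]]:
    targets = [{sex: 0 for sex in counts} for _ in range(n_folds)]
    for sex, n in counts.items():
        for i in range(n):
            targets[i % n_folds][sex] += 1
    return targets


def assign_folds(
    labels: np.ndarray,
    n_folds: int = 10,
    target_counts: list[dict[str, int]] | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Deal shuffled rows to folds matching per-fold class counts exactly.

    With 62 female / 50 male rows and ten folds the study's printed fold
    table is the default target; otherwise rows are balanced round-robin
    (per-class fold sizes differ by at most one).
    """
    labels = np.asarray(labels)
    counts = {sex: int(np.sum(labels == sex)) for sex in (FEMALE, MALE)}
    if target_counts is None:
        if n_folds == 10 and counts == {"F": 62, "M": 50}:
            target_counts = [{"F": f, "M": m} for f, m in TABLE1_FOLD_COUNTS]
        else:
            target_counts = _round_robin_targets(counts, n_folds)
    if len(target_counts) != n_folds:
        raise ValueError("target_counts length must equal n_folds")
    for sex, n in counts.items():
        total = sum(t.get(sex, 0) for t in target_counts)
        if total != n:
            raise ValueError(
                f"target counts for class {sex} sum to {total}, data has {n}"
            )

    rng = np.random.default_rng(seed)
    assignments = np.full(len(labels), -1, dtype=int)
    for sex in counts:
        idx = np.where(labels == sex)[0]
        rng.shuffle(idx)
        pos = 0
        for fold, tgt in enumerate(target_counts):
            take = tgt.get(sex, 0)
            assignments[idx[pos : pos + take]] = fold
            pos += take
    return FoldPlan(n_folds, assignments, [dict(t) for t in target_counts])


# ---------------------------------------------------------------------------
# image preprocessing

_LUMA = np.array([0.2125, 0.7154, 0.0721])  # ITU-R 709 luminance weights


def preprocess_image(raw: np.ndarray, side: int = 28) -> np.ndarray:
    """Grayscale, resize to ``side`` x ``side`` (bilinear), map to [-1, 1].

    Integer input is assumed 8-bit ([0, 255]); float input is assumed
    already in [0, 1]. The final affine map (x - 0.5) / 0.5 centres the
    unit-interval image at zero, matching the study's tensor normalization
    with mean and SD 0.5.
    """
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(raw.dtype, np.integer):
        img = raw.astype(float) / 255.0
    else:
        img = raw.astype(float)
    if img.ndim == 3:
        if img.shape[2] == 1:
            img = img[:, :, 0]
        elif img.shape[2] == 3:
            img = img @ _LUMA
        else:
            raise ValueError(f"unsupported channel count {img.shape[2]}")
    elif img.ndim != 2:
        raise ValueError("image must be 2-D or (H, W, C)")
    if img.shape != (side, side):
        img = _sk_resize(img, (side, side), order=1, anti_aliasing=False,
                         preserve_range=True)
    return (img - 0.5) / 0.5
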