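"""Benchmark harness for the six classifier families.

Five canonical models (MLP, KNN, Gaussian NB, random forest, RBF-kernel
SVM) come from scikit-learn; the sixth is the package's own KAN wrapped in
a scikit-learn-style estimator. Two evaluation protocols are provided:

* pooled ten-fold on the tabular data — hyperparameters tuned by rotating
  ten-fold accuracy on the same fold plan, then each fold predicted once
  by a model trained on the other nine, all predictions pooled into a
  single confusion matrix (the study's procedure, optimistic by design;
  see the methods note);
* hold-out on image features — tuning by ten-fold cross-validation inside
  the training partition only, one final fit, one evaluation on the
  untouched test partition.

Scalers are always fitted inside each training split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .evaluation import ConfusionMatrix, confusion
from .kan import KanSpec, KanTrainConfig, predict_kan, train_kan
from .preprocessing import FoldPlan, assign_folds
from .synthetic import MorphometricTable

__all__ = [
    "ModelSpec",
    "CvResult",
    "KanClassifier",
    "DEFAULT_GRIDS",
    "make_model",
    "grid_search_cv",
    "pooled_fold_predictions",
    "holdout_fit_predict",
]

#: default tuning grids (config-overridable); NB is never tuned
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "mlp": {"hidden_layer_sizes": [(50,), (100,), (100, 50)],
            "alpha": [1e-4, 1e-3]},
    "knn": {"n_neighbors": [3, 5, 7, 9], "metric": ["euclidean", "manhattan"]},
    "gnb": {},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
    "kan": {"grid_size": [5], "learning_rate": [1e-3, 1e-2]},
}


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    tuning_grid: dict | None = None  # None -> DEFAULT_GRIDS[family]

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.tuning_grid is None:
            self.tuning_grid = dict(DEFAULT_GRIDS[self.family])
        if self.family == "gnb" and self.tuning_grid:
            raise ValueError("NB models are not tuned")


@dataclass
class CvResult:
    best_hyperparameters: dict
    candidate_scores: list[tuple[dict, float]]
    predictions: np.ndarray  # pooled per-sample predicted labels, row order
    cm: ConfusionMatrix


class KanClassifier:
    """scikit-learn-style front end for the spline-edge network."""

    def __init__(self, hidden_dims=(256, 128, 64, 32), grid_size=5,
                 spline_order=3, learning_rate=1e-3, max_epochs=200,
                 seed=0) -> None:
        self.hidden_dims = tuple(hidden_dims)
        self.grid_size = grid_size
        self.spline_order = spline_order
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.seed = seed
        self._model = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "KanClassifier":
        dims = (x.shape[1], *self.hidden_dims, 1)
        spec = KanSpec(dims, self.grid_size, self.spline_order)
        cfg = KanTrainConfig(learning_rate=self.learning_rate,
                             max_epochs=self.max_epochs, seed=self.seed)
        self._model, self.history_ = train_kan(spec, x, y, cfg)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("fit before predict")
        labels, _ = predict_kan(self._model, x)
        return labels

    def predict_proba_male(self, x: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(x)


def make_model(family: str, params: dict, seed: int = 0):
    params = dict(params)
    if family == "mlp":
        return MLPClassifier(random_state=seed, max_iter=1000, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "gnb":
        return GaussianNB(**params)
    if family == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "svm":
        return SVC(kernel=params.pop("kernel", "rbf"), random_state=seed,
                   **params)
    if family == "kan":
        return KanClassifier(seed=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


def _fit_scale(x: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    if kind == "standard":
        center = x.mean(axis=0)
        scale = x.std(axis=0)
    elif kind == "minmax":
        center = x.min(axis=0)
        scale = x.max(axis=0) - center
    elif kind == "none":
        return np.zeros(x.shape[1]), np.ones(x.shape[1])
    else:
        raise ValueError(f"unknown scale kind {kind!r}")
    scale = np.where(scale == 0, 1.0, scale)
    return center, scale


def _grid_candidates(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def _rotated_accuracy(
    family: str, params: dict, x: np.ndarray, y: np.ndarray,
    folds: FoldPlan, scale_kind: str, seed: int,
) -> float:
    """Mean test-fold accuracy of one candidate over the fold rotation."""
    accs = []
    for f in range(folds.n_folds):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        center, scale = _fit_scale(x[tr], scale_kind)
        model = make_model(family, params, seed=seed)
        model.fit((x[tr] - center) / scale, y[tr])
        pred = model.predict((x[te] - center) / scale)
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


def grid_search_cv(
    spec: ModelSpec,
    table: MorphometricTable | np.ndarray,
    folds: FoldPlan,
    scale_kind: str = "standard",
    labels: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Pick the candidate with highest mean rotated-fold accuracy.

    Ties break toward the first candidate in grid order. Accepts a
    MorphometricTable or a raw feature matrix plus labels.
    """
    if isinstance(table, MorphometricTable):
        x, y = table.values, table.labels
    else:
        x, y = np.asarray(table, dtype=float), np.asarray(labels)
    candidates = _grid_candidates(spec.tuning_grid)
    merged = [dict(spec.hyperparameters, **c) for c in candidates]
    if len(merged) == 1:
        return merged[0], [(merged[0], float("nan"))]
    scores = [
        (params, _rotated_accuracy(spec.family, params, x, y, folds,
                                   scale_kind, seed))
        for params in merged
    ]
    best = max(scores, key=lambda item: item[1])  # max keeps first on ties
    return best[0], scores


def pooled_fold_predictions(
    spec: ModelSpec,
    table: MorphometricTable | np.ndarray,
    folds: FoldPlan,
    scale_kind: str = "standard",
    labels: np.ndarray | None = None,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> CvResult:
    """Each fold predicted once by a model trained on the other nine;
    all predictions pooled into one confusion matrix."""
    if isinstance(table, MorphometricTable):
        x, y = table.values, table.labels
    else:
        x, y = np.asarray(table, dtype=float), np.asarray(labels)
    counts = np.bincount(folds.assignments[folds.assignments >= 0],
                         minlength=folds.n_folds)
    if (folds.assignments < 0).any() or counts.sum() != len(y):
        raise ValueError("fold plan is not a partition of the rows")
    params = hyperparameters if hyperparameters is not None else spec.hyperparameters
    predictions = np.empty(len(y), dtype=object)
    for f in range(folds.n_folds):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        center, scale = _fit_scale(x[tr], scale_kind)
        model = make_model(spec.family, params, seed=seed)
        model.fit((x[tr] - center) / scale, y[tr])
        predictions[te] = model.predict((x[te] - center) / scale)
    predictions = predictions.astype(str)
    return CvResult(dict(params), [], predictions, confusion(y, predictions))


def holdout_fit_predict(
    spec: ModelSpec,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
    tuning_folds: int = 10,
    scale_kind: str = "standard",
    seed: int = 0,
    train_ids: np.ndarray | None = None,
    test_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, ConfusionMatrix, dict]:
    """Tune inside the training features only, fit once, evaluate once.

    Returns (test predictions, confusion matrix, chosen hyperparameters).
    Providing row ids enables an explicit leakage check.
    """
    if train_ids is not None and test_ids is not None:
        overlap = np.intersect1d(train_ids, test_ids)
        if overlap.size:
            raise ValueError(
                f"leakage: {overlap.size} row id(s) appear in both "
                f"train and test partitions"
            )
    x_tr = np.asarray(train_features, dtype=float)
    y_tr = np.asarray(train_labels)
    x_te = np.asarray(test_features, dtype=float)
    y_te = np.asarray(test_labels)

    folds = assign_folds(y_tr, n_folds=tuning_folds, seed=seed)
    best, _ = grid_search_cv(spec, x_tr, folds, scale_kind, labels=y_tr,
                             seed=seed)
    center, scale = _fit_scale(x_tr, scale_kind)
    model = make_model(spec.family, best, seed=seed)
    model.fit((x_tr - center) / scale, y_tr)
    pred = model.predict((x_te - center) / scale)
    return pred, confusion(y_te, pred), best
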