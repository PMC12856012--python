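"""Kolmogorov-Arnold network (KAN) for binary sex classification.

Every edge of a KAN layer carries a learnable univariate function: a
linear combination of B-spline basis functions over a fixed grid, added to
a smooth "base" path (silu activation times a weight). With grid size G
and spline order S each edge owns G + S spline coefficients; the basis is
evaluated by the Cox-de Boor recursion over a uniformly extended knot
vector, so inputs slightly outside the nominal domain still fall on
defined knots.

The default classifier stacks layers [input, 256, 128, 64, 32, 1] with a
sigmoid output head trained by binary cross-entropy (full-batch Adam or
SGD, plateau learning-rate decay, early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineGrid",
    "KanLayer",
    "KanSpec",
    "KanTrainConfig",
    "KanModel",
    "bspline_basis",
    "kan_layer_forward",
    "train_kan",
    "predict_kan",
]


@dataclass(frozen=True)
class SplineGrid:
    """Uniform B-spline grid: G intervals on [low, high], order S."""

    grid_size: int = 5
    spline_order: int = 3
    low: float = -1.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if self.spline_order < 0:
            raise ValueError("spline_order must be >= 0")
        if not self.high > self.low:
            raise ValueError("domain must satisfy high > low")

    @property
    def n_basis(self) -> int:
        return self.grid_size + self.spline_order

    @property
    def knots(self) -> np.ndarray:
        """Extended knot vector, G + 2S + 1 non-decreasing values."""
        h = (self.high - self.low) / self.grid_size
        idx = np.arange(-self.spline_order,
                        self.grid_size + self.spline_order + 1)
        return self.low + h * idx


def _basis_orders(x: np.ndarray, grid: SplineGrid) -> list[np.ndarray]:
    """Cox-de Boor pyramid: basis values for orders 0..S, flattened x."""
    t = grid.knots
    b = ((x[:, None] >= t[None, :-1]) & (x[:, None] < t[None, 1:])).astype(float)
    orders = [b]
    for r in range(1, grid.spline_order + 1):
        left = (x[:, None] - t[None, : -(r + 1)]) / (t[r:-1] - t[: -(r + 1)])
        right = (t[None, r + 1 :] - x[:, None]) / (t[r + 1 :] - t[1:-r])
        b = left * b[:, :-1] + right * b[:, 1:]
        orders.append(b)
    return orders


def bspline_basis(x: np.ndarray, grid: SplineGrid) -> np.ndarray:
    """B-spline basis values, shape ``x.shape + (G + S,)``.

    Inside the domain the order-S basis is a partition of unity; outside
    the extended knot span all values are zero (the base path carries
    those inputs).
    """
    x = np.asarray(x, dtype=float)
    flat = x.reshape(-1)
    b = _basis_orders(flat, grid)[-1][:, : grid.n_basis]
    return b.reshape(*x.shape, grid.n_basis)


def bspline_basis_and_deriv(
    x: np.ndarray, grid: SplineGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Basis values and their first derivatives with respect to x."""
    x = np.asarray(x, dtype=float)
    flat = x.reshape(-1)
    orders = _basis_orders(flat, grid)
    k = grid.n_basis
    b = orders[-1][:, :k]
    s = grid.spline_order
    if s == 0:
        db = np.zeros_like(b)
    else:
        t = grid.knots
        bm1 = orders[-2]
        denom1 = t[s:-1] - t[:-(s + 1)]
        denom2 = t[s + 1 :] - t[1:-s]
        db = s * (bm1[:, :-1] / denom1 - bm1[:, 1:] / denom2)
        db = db[:, :k]
    return b.reshape(*x.shape, k), db.reshape(*x.shape, k)


def _silu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """silu(x) = x * sigmoid(x) and its derivative."""
    sig = 1.0 / (1.0 + np.exp(-x))
    return x * sig, sig * (1.0 + x * (1.0 - sig))


class KanLayer:
    """One KAN layer: out_j = sum_i Wb[j,i] silu(x_i)
    + sum_{i,k} Ws[j,i,k] B_k(x_i)."""

    def __init__(self, in_dim: int, out_dim: int, grid: SplineGrid,
                 rng: np.random.Generator | None = None) -> None:
        if in_dim < 1 or out_dim < 1:
            raise ValueError("layer dimensions must be positive")
        self.in_dim, self.out_dim, self.grid = in_dim, out_dim, grid
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(in_dim)
        self.base_weights = rng.uniform(-scale, scale, (out_dim, in_dim))
        self.spline_weights = rng.uniform(
            -0.1 * scale, 0.1 * scale, (out_dim, in_dim, grid.n_basis)
        )
        self.d_base = np.zeros_like(self.base_weights)
        self.d_spline = np.zeros_like(self.spline_weights)
        self._cache = None

    @property
    def params(self):
        return [(self.base_weights, self.d_base),
                (self.spline_weights, self.d_spline)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_dim:
            raise ValueError(
                f"input has shape {x.shape}, layer expects (n, {self.in_dim})"
            )
        sil, dsil = _silu(x)
        basis, dbasis = bspline_basis_and_deriv(x, self.grid)
        out = sil @ self.base_weights.T
        out += np.einsum("nik,oik->no", basis, self.spline_weights,
                         optimize=True)
        self._cache = (sil, dsil, basis, dbasis)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        sil, dsil, basis, dbasis = self._cache
        self.d_base[...] = g.T @ sil
        self.d_spline[...] = np.einsum("no,nik->oik", g, basis, optimize=True)
        dx = (g @ self.base_weights) * dsil
        dx += np.einsum("no,oik,nik->ni", g, self.spline_weights, dbasis,
                        optimize=True)
        return dx


def kan_layer_forward(x: np.ndarray, layer: KanLayer) -> np.ndarray:
    """Functional forward pass through one layer (n, in) -> (n, out)."""
    return layer.forward(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class KanSpec:
    """Architecture: layer widths ending in a single sigmoid output."""

    layer_dims: tuple[int, ...] = (11, 256, 128, 64, 32, 1)
    grid_size: int = 5
    spline_order: int = 3
    domain: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 2:
            raise ValueError("need at least input and output layers")
        if self.layer_dims[-1] != 1:
            raise ValueError("binary classifier requires final dim 1")

    def grid(self) -> SplineGrid:
        return SplineGrid(self.grid_size, self.spline_order, *self.domain)


@dataclass(frozen=True)
class KanTrainConfig:
    optimizer: str = "adam"  # or "sgd"
    learning_rate: float = 1e-3
    max_epochs: int = 200
    early_stop_patience: int = 10
    early_stop_delta: float = 1e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be adam or sgd")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patiences must be >= 1")


class KanModel:
    def __init__(self, spec: KanSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        grid = spec.grid()
        self.layers = [
            KanLayer(spec.layer_dims[i], spec.layer_dims[i + 1], grid, rng)
            for i in range(len(spec.layer_dims) - 1)
        ]

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of shape (n,) for inputs (n, input_dim)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.spec.layer_dims[0]:
            raise ValueError(
                f"features have shape {x.shape}, model expects "
                f"(n, {self.spec.layer_dims[0]})"
            )
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def loss_and_grads(self, x: np.ndarray, y01: np.ndarray) -> float:
        """Mean binary cross-entropy; fills every layer's gradient arrays."""
        z = self.forward(x)
        # stable BCE-with-logits: softplus(z) - y z
        loss = float(np.mean(np.logaddexp(0.0, z) - y01 * z))
        p = 1.0 / (1.0 + np.exp(-z))
        g = ((p - y01) / len(y01))[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.forward(x)))


def _labels_to01(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        unknown = set(np.unique(labels)) - {"F", "M"}
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
        return (labels == "M").astype(float)
    y = labels.astype(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("numeric labels must be binary 0/1")
    return y


def train_kan(
    spec: KanSpec,
    features: np.ndarray,
    labels: np.ndarray,
    cfg: KanTrainConfig = KanTrainConfig(),
) -> tuple[KanModel, dict]:
    """Full-batch training with plateau LR decay and early stopping.

    Returns the trained model and a history dict with per-epoch ``loss``
    and ``lr``. The learning rate is multiplied by ``plateau_factor``
    whenever the loss fails to improve for ``plateau_patience`` epochs;
    training halts when it fails to improve by more than
    ``early_stop_delta`` for ``early_stop_patience`` epochs.
    """
    x = np.asarray(features, dtype=float)
    y = _labels_to01(labels)
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    model = KanModel(spec, seed=cfg.seed)

    from ._nn import SGD, Adam

    opt_cls = Adam if cfg.optimizer == "adam" else SGD
    opt = opt_cls(model.params, lr=cfg.learning_rate)

    losses: list[float] = []
    lrs: list[float] = []
    best = np.inf
    es_stale = 0
    plateau_best = np.inf
    plateau_stale = 0
    for epoch in range(cfg.max_epochs):
        loss = model.loss_and_grads(x, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        opt.step()
        losses.append(loss)
        lrs.append(opt.lr)

        if loss < plateau_best - 1e-8:
            plateau_best = loss
            plateau_stale = 0
        else:
            plateau_stale += 1
            if plateau_stale >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                plateau_stale = 0

        if loss < best - cfg.early_stop_delta:
            best = loss
            es_stale = 0
        else:
            es_stale += 1
            if es_stale >= cfg.early_stop_patience:
                break
    return model, {"loss": losses, "lr": lrs}


def predict_kan(
    model: KanModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and probabilities; male iff P(male) >= 0.5."""
    proba = model.predict_proba(np.asarray(features, dtype=float))
    labels = np.where(proba >= 0.5, "M", "F")
    return labels, proba
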