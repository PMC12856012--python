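"""Convolutional autoencoder (CAE) and stacked CAE (SCAE) feature extractors.

Stage one compresses 28x28 single-channel images through two conv layers
into a 128 x 10 x 10 code (12,800 features flattened); stage two trains a
second autoencoder on those codes and yields a 512 x 6 x 6 code (18,432
features). Both are trained to minimize mean squared reconstruction error
with Adam (lr 1e-3, batch 16), stopping early when the training loss fails
to improve by more than a delta for a patience of epochs.

The encoder layer shapes are the only hard architectural constraints the
benchmark imposes (two conv layers per stage; 128-channel code feeding
stage two; flattened dims 12,800 and 18,432); every layer spec is
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .synthetic import ImageSet

__all__ = [
    "ConvLayerSpec",
    "AutoencoderSpec",
    "TrainConfig",
    "FeatureMatrix",
    "CAEModel",
    "build_cae",
    "train_autoencoder",
    "extract_features",
    "build_scae_features",
    "LeakageAudit",
]

CAE_FEATURE_DIM = 12_800  # 128 channels x 10 x 10
SCAE_FEATURE_DIM = 18_432  # 512 channels x 6 x 6


@dataclass(frozen=True)
class ConvLayerSpec:
    in_channels: int
    out_channels: int
    kernel: int
    stride: int = 1
    padding: int = 0
    output_padding: int = 0  # transposed-conv layers only

    def __post_init__(self) -> None:
        if min(self.in_channels, self.out_channels, self.kernel, self.stride) < 1:
            raise ValueError("channels, kernel and stride must be positive")
        if self.padding < 0 or self.output_padding < 0:
            raise ValueError("padding must be non-negative")


@dataclass(frozen=True)
class AutoencoderSpec:
    encoder: tuple[ConvLayerSpec, ...]
    decoder: tuple[ConvLayerSpec, ...]
    input_shape: tuple[int, int, int]  # (channels, H, W)
    flattened_feature_dim: int

    def code_shape(self) -> tuple[int, int, int]:
        c, h, w = self.input_shape
        for layer in self.encoder:
            h = _nn.conv_out_size(h, layer.kernel, layer.stride, layer.padding)
            w = _nn.conv_out_size(w, layer.kernel, layer.stride, layer.padding)
            c = layer.out_channels
        return c, h, w

    def output_shape(self) -> tuple[int, int, int]:
        c, h, w = self.code_shape()
        for layer in self.decoder:
            h = _nn.convt_out_size(h, layer.kernel, layer.stride, layer.padding,
                                   layer.output_padding)
            w = _nn.convt_out_size(w, layer.kernel, layer.stride, layer.padding,
                                   layer.output_padding)
            c = layer.out_channels
        return c, h, w


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 5
    early_stop_delta: float = 1e-3
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.early_stop_delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class FeatureMatrix:
    """Flattened encoder activations with labels and partition tags."""

    values: np.ndarray  # (n, d)
    labels: np.ndarray
    partition: np.ndarray
    source: str  # "cae" or "scae"

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[mask], self.labels[mask],
                             self.partition[mask], self.source)


class LeakageAudit:
    """Records which row indices each training stage consumed."""

    def __init__(self) -> None:
        self.trained_on: dict[str, np.ndarray] = {}

    def record(self, stage: str, indices: np.ndarray) -> None:
        self.trained_on[stage] = np.asarray(indices).copy()


def build_cae(stage: str = "first") -> AutoencoderSpec:
    """Default two-conv-layer autoencoder spec for the given stage.

    first: 1x28x28 -> 64x14x14 -> 128x10x10 (12,800 flattened), mirrored
    transposed-conv decoder ending in a sigmoid reconstruction.
    second: 128x10x10 -> 256x10x10 -> 512x6x6 (18,432 flattened), decoder
    reconstructing the 128x10x10 input.
    """
    if stage == "first":
        spec = AutoencoderSpec(
            encoder=(
                ConvLayerSpec(1, 64, kernel=3, stride=2, padding=1),
                ConvLayerSpec(64, 128, kernel=5, stride=1, padding=0),
            ),
            decoder=(
                ConvLayerSpec(128, 64, kernel=5, stride=1, padding=0),
                ConvLayerSpec(64, 1, kernel=3, stride=2, padding=1,
                              output_padding=1),
            ),
            input_shape=(1, 28, 28),
            flattened_feature_dim=CAE_FEATURE_DIM,
        )
    elif stage == "second":
        spec = AutoencoderSpec(
            encoder=(
                ConvLayerSpec(128, 256, kernel=3, stride=1, padding=1),
                ConvLayerSpec(256, 512, kernel=5, stride=1, padding=0),
            ),
            decoder=(
                ConvLayerSpec(512, 256, kernel=5, stride=1, padding=0),
                ConvLayerSpec(256, 128, kernel=3, stride=1, padding=1),
            ),
            input_shape=(128, 10, 10),
            flattened_feature_dim=SCAE_FEATURE_DIM,
        )
    else:
        raise ValueError(f"stage must be 'first' or 'second', got {stage!r}")
    return validate_spec(spec)


def validate_spec(spec: AutoencoderSpec) -> AutoencoderSpec:
    c, h, w = spec.code_shape()
    achieved = c * h * w
    if achieved != spec.flattened_feature_dim:
        raise ValueError(
            f"encoder flattens to {achieved} features "
            f"({c}x{h}x{w}), spec targets {spec.flattened_feature_dim}"
        )
    if spec.output_shape() != spec.input_shape:
        raise ValueError(
            f"decoder output shape {spec.output_shape()} does not match "
            f"encoder input shape {spec.input_shape}"
        )
    return spec


class CAEModel:
    """Numpy convolutional autoencoder with ReLU hidden layers and a
    sigmoid reconstruction head."""

    def __init__(self, spec: AutoencoderSpec, seed: int = 0) -> None:
        validate_spec(spec)
        self.spec = spec
        rng = np.random.default_rng(seed)
        enc_layers = []
        for layer in spec.encoder:
            enc_layers.append(_nn.Conv2D(layer.in_channels, layer.out_channels,
                                         layer.kernel, layer.stride,
                                         layer.padding, rng=rng))
            enc_layers.append(_nn.ReLU())
        dec_layers = []
        for i, layer in enumerate(spec.decoder):
            dec_layers.append(_nn.ConvTranspose2D(
                layer.in_channels, layer.out_channels, layer.kernel,
                layer.stride, layer.padding, layer.output_padding, rng=rng))
            last = i == len(spec.decoder) - 1
            dec_layers.append(_nn.Sigmoid() if last else _nn.ReLU())
        self.encoder = _nn.Sequential(enc_layers)
        self.decoder = _nn.Sequential(dec_layers)
        self.net = _nn.Sequential(enc_layers + dec_layers)

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)


def _as_batch_input(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:  # (n, H, W) -> add channel axis
        images = images[:, None, :, :]
    return images


def train_autoencoder(
    spec: AutoencoderSpec,
    data: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    target: np.ndarray | None = None,
) -> tuple[CAEModel, list[float]]:
    """Train to minimize mean squared reconstruction error.

    ``data`` is the network input ((n, H, W) or (n, C, H, W)); ``target``
    defaults to the input itself and must live in [0, 1] to match the
    sigmoid head (for stage one, pass the [0,1] remap of the [-1,1]
    images). Returns the model and the per-epoch mean training loss;
    stops early when the loss fails to improve by more than
    ``early_stop_delta`` for ``early_stop_patience`` consecutive epochs.
    """
    x = _as_batch_input(data)
    if x.shape[0] == 0:
        raise ValueError("empty training dataset")
    y = x if target is None else _as_batch_input(target)
    if y.shape != x.shape and y.shape[1:] != x.shape[1:]:
        raise ValueError("target shape does not match input shape")

    model = CAEModel(spec, seed=cfg.seed)
    opt = _nn.Adam(model.net.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = x.shape[0]
    losses: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = model.net.forward(x[idx])
            loss, grad = _nn.mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {epoch}"
                )
            model.net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        losses.append(epoch_loss)
        if epoch_loss < best - cfg.early_stop_delta:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    return model, losses


def extract_features(
    model: CAEModel,
    images: np.ndarray,
    labels: np.ndarray,
    partition: np.ndarray,
    source: str = "cae",
    batch_size: int = 64,
) -> FeatureMatrix:
    """Flattened encoder activation per image, row order preserved."""
    x = _as_batch_input(images)
    if x.shape[1:] != model.spec.input_shape:
        raise ValueError(
            f"images have shape {x.shape[1:]}, encoder expects "
            f"{model.spec.input_shape}"
        )
    chunks = []
    for start in range(0, x.shape[0], batch_size):
        code = model.encode(x[start : start + batch_size])
        chunks.append(code.reshape(code.shape[0], -1))
    return FeatureMatrix(np.concatenate(chunks), np.asarray(labels),
                         np.asarray(partition), source)


def build_scae_features(
    imageset: ImageSet,
    cfg: TrainConfig = TrainConfig(),
    first_spec: AutoencoderSpec | None = None,
    second_spec: AutoencoderSpec | None = None,
    audit: LeakageAudit | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Train both stages on the training partition; emit CAE and SCAE
    feature matrices covering all images.

    Stage one consumes [-1,1]-normalized pixels and reconstructs their
    [0,1] remap through the sigmoid head. Stage two consumes the stage-one
    ReLU codes rescaled by their maximum over the training codes (so the
    sigmoid head can reconstruct them) and reconstructs the same rescaled
    codes. Test-partition images are touched only at extraction time.
    """
    first_spec = first_spec or build_cae("first")
    second_spec = second_spec or build_cae("second")
    part = np.asarray(imageset.partition)
    train_mask = part == "train"
    if not train_mask.any():
        raise ValueError("no training-partition images")

    x_all = np.asarray(imageset.pixels, dtype=float)
    x_all = (x_all - 0.5) / 0.5  # [0,1] pixels -> [-1,1] network input
    x_train = x_all[train_mask]
    if audit is not None:
        audit.record("cae", np.where(train_mask)[0])

    model1, _ = train_autoencoder(first_spec, x_train, cfg,
                                  target=(x_train + 1.0) / 2.0)
    cae_feats = extract_features(model1, x_all, imageset.labels,
                                 imageset.partition, source="cae")

    # unflattened stage-one codes feed stage two
    c, h, w = first_spec.code_shape()
    codes_all = cae_feats.values.reshape(-1, c, h, w)
    code_scale = float(codes_all[train_mask].max())
    if code_scale <= 0:
        code_scale = 1.0
    codes01 = codes_all / code_scale
    if audit is not None:
        audit.record("scae", np.where(train_mask)[0])
    cfg2 = TrainConfig(cfg.learning_rate, cfg.batch_size, cfg.max_epochs,
                       cfg.early_stop_patience, cfg.early_stop_delta,
                       cfg.shuffle, cfg.seed + 1)
    model2, _ = train_autoencoder(second_spec, codes01[train_mask], cfg2)
    scae_feats = extract_features(model2, codes01, imageset.labels,
                                  imageset.partition, source="scae")
    return cae_feats, scae_feats
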