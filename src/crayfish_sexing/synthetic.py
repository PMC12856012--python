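"""Synthetic morphometric tables and crayfish-like image sets.

The real study data are ~100 animals with 11 numeric body measurements
(weight, carapace/abdomen/cheliped dimensions) and ~1,300 grayscale photos
downscaled to 28x28. This module emits stand-ins with the same statistical
skeleton: sex-conditional Gaussian morphometrics with a configurable
standardized mean separation (Cohen's d), MCAR missingness and injected
outliers; and 28x28 grayscale blob images whose body elongation and claw
size depend on sex. Only the pipeline's statistical behaviour is emulated,
not crayfish anatomy.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "TabularSimSpec",
    "ImageSimSpec",
    "MorphometricTable",
    "ImageSet",
    "FormatError",
    "MORPHOMETRIC_NAMES",
    "STUDY_TABULAR_COUNTS",
    "STUDY_IMAGE_COUNTS",
    "STUDY_IMAGE_TEST_COUNTS",
    "class_ratio",
    "generate_tabular",
    "generate_images",
    "write_table",
    "read_table",
    "write_images",
    "read_images",
]

FEMALE = "F"
MALE = "M"

#: the eight measurements taken on each animal, plus generic extras up to p
MORPHOMETRIC_NAMES = [
    "weight",
    "carapace_length",
    "carapace_width",
    "abdomen_length",
    "abdomen_width",
    "cheliped_length",
    "cheliped_width",
    "cheliped_height",
]

#: study bookkeeping: 62 female / 50 male animals measured, 717 female /
#: 560 male photos, photo test split 216 female / 166 male (of 1,277)
STUDY_TABULAR_COUNTS = {"F": 62, "M": 50}
STUDY_IMAGE_COUNTS = {"F": 717, "M": 560}
STUDY_IMAGE_TEST_COUNTS = {"F": 216, "M": 166}

# plausible per-feature location/scale so columns live on morphometric
# magnitudes (grams / millimetres); affine, so Cohen's d is unaffected
_BASE_MEAN = np.array([45.0, 55.0, 28.0, 60.0, 25.0, 70.0, 18.0, 12.0])
_BASE_SD = np.array([12.0, 8.0, 4.0, 9.0, 4.0, 15.0, 4.0, 2.5])


class FormatError(ValueError):
    """Raised when an on-disk table or image manifest is malformed."""


def class_ratio(n_minor: int, n_major: int, decimals: int = 3) -> float:
    """Minority:majority class ratio as printed in dataset summaries."""
    return round(n_minor / n_major, decimals)


def _feature_names(p: int) -> list[str]:
    names = list(MORPHOMETRIC_NAMES[:p])
    for i in range(len(names), p):
        names.append(f"extra_{i - len(MORPHOMETRIC_NAMES) + 1}")
    return names


def _feature_scales(p: int) -> tuple[np.ndarray, np.ndarray]:
    k = len(_BASE_MEAN)
    mean = np.concatenate([_BASE_MEAN, np.full(max(p - k, 0), 10.0)])[:p]
    sd = np.concatenate([_BASE_SD, np.full(max(p - k, 0), 3.0)])[:p]
    return mean, sd


@dataclass(frozen=True)
class TabularSimSpec:
    """Parameters of the sex-conditional Gaussian morphometric generator.

    ``effect_size`` is the standardized per-feature mean separation between
    sexes (Cohen's d, unitless). ``missing_rate`` cells are blanked
    completely at random; ``outlier_rate`` of the remaining cells are
    displaced by ``outlier_scale`` within-class standard deviations.
    """

    n_female: int = 62
    n_male: int = 50
    n_features: int = 11
    effect_size: float = 1.0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("class counts must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for name in ("missing_rate", "outlier_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.outlier_scale < 0:
            raise ValueError("outlier_scale must be non-negative")


@dataclass(frozen=True)
class ImageSimSpec:
    """Parameters of the sex-dimorphic blob image generator.

    Each image is an ellipse "body" plus two frontal "claw" protrusions on
    a dark background; males are more elongated with larger claws. With
    ``noise_sd`` 0 each class is a single noiseless template.
    """

    n_female: int = 717
    n_male: int = 560
    side: int = 28
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("class counts must be >= 1")
        if self.side < 8:
            raise ValueError("side must be >= 8 pixels")
        if self.noise_sd < 0 or self.noise_sd > 1:
            raise ValueError("noise_sd must lie in [0, 1]")


@dataclass
class MorphometricTable:
    """n x p numeric table with missingness mask and per-row sex labels."""

    values: np.ndarray
    missing_mask: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal row count")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must equal column count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MorphometricTable":
        return MorphometricTable(
            self.values.copy(),
            self.missing_mask.copy(),
            self.labels.copy(),
            list(self.feature_names),
        )


@dataclass
class ImageSet:
    """Stack of single-channel images with sex labels and train/test tags."""

    pixels: np.ndarray  # (n, side, side) in [0, 1]
    labels: np.ndarray  # per-image sex in {F, M}
    partition: np.ndarray  # per-image tag in {train, test}

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.labels = np.asarray(self.labels)
        self.partition = np.asarray(self.partition)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (n, side, side); one channel only")
        if self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValueError("images must be square")
        n = self.pixels.shape[0]
        if len(self.labels) != n or len(self.partition) != n:
            raise ValueError("labels/partition length must equal image count")

    @property
    def side(self) -> int:
        return self.pixels.shape[1]

    def subset(self, mask: np.ndarray) -> "ImageSet":
        return ImageSet(self.pixels[mask], self.labels[mask], self.partition[mask])


def generate_tabular(spec: TabularSimSpec) -> MorphometricTable:
    """Draw a sex-labelled morphometric table per ``spec``.

    Class means are separated by ``effect_size`` within-class SDs on every
    feature; missing cells are MCAR; outliers displace non-missing cells by
    ``outlier_scale`` SDs with random sign. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_female + spec.n_male
    p = spec.n_features
    labels = np.array([FEMALE] * spec.n_female + [MALE] * spec.n_male)
    mean, sd = _feature_scales(p)

    z = rng.standard_normal((n, p))
    shift = np.where(labels[:, None] == MALE, spec.effect_size, 0.0)
    values = mean + sd * (z + shift)

    missing = rng.random((n, p)) < spec.missing_rate
    outlier_cells = (rng.random((n, p)) < spec.outlier_rate) & ~missing
    signs = np.where(rng.random((n, p)) < 0.5, -1.0, 1.0)
    values = np.where(outlier_cells, values + signs * spec.outlier_scale * sd, values)
    values = np.where(missing, np.nan, values)

    return MorphometricTable(values, missing, labels, _feature_names(p))


def _blob_template(side: int, sex: str) -> np.ndarray:
    """Noiseless class template: ellipse body + two claw protrusions.

    Male bodies are more elongated (higher eccentricity) and carry larger
    claws; intensities are binary {background, foreground}.
    """
    bg, fg = 0.1, 0.9
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2.0
    if sex == MALE:
        a, b, claw_r = 0.40, 0.16, 0.11
    else:
        a, b, claw_r = 0.32, 0.24, 0.06
    a, b, claw_r = a * side, b * side, claw_r * side
    body = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    # claws sit ahead of the body tip, one on each side
    ty = cy - a * 0.95
    off = max(b * 0.9, 2.0)
    claws = ((yy - ty) ** 2 + (xx - (cx - off)) ** 2 <= claw_r**2) | (
        (yy - ty) ** 2 + (xx - (cx + off)) ** 2 <= claw_r**2
    )
    img = np.where(body | claws, fg, bg)
    return img


def _default_test_counts(n_female: int, n_male: int) -> dict[str, int]:
    if {"F": n_female, "M": n_male} == STUDY_IMAGE_COUNTS:
        return dict(STUDY_IMAGE_TEST_COUNTS)
    return {"F": round(0.3 * n_female), "M": round(0.3 * n_male)}


def generate_images(
    spec: ImageSimSpec, test_counts: dict[str, int] | None = None
) -> ImageSet:
    """Draw sex-dimorphic blob images and tag a held-out test partition.

    ``test_counts`` gives per-class test-set sizes; by default the study's
    printed partition is used when the class counts match the study's
    (717 F / 560 M -> 216 F / 166 M test), else round(0.3 * n) per class.
    """
    rng = np.random.default_rng(spec.seed)
    counts = {"F": spec.n_female, "M": spec.n_male}
    if test_counts is None:
        test_counts = _default_test_counts(spec.n_female, spec.n_male)
    for sex, c in test_counts.items():
        if not 0 <= c <= counts[sex]:
            raise ValueError(f"test count for {sex} out of range")

    pixels, labels, partition = [], [], []
    for sex in (FEMALE, MALE):
        template = _blob_template(spec.side, sex)
        n = counts[sex]
        imgs = template[None, :, :] + spec.noise_sd * rng.standard_normal(
            (n, spec.side, spec.side)
        )
        np.clip(imgs, 0.0, 1.0, out=imgs)
        tags = np.array(["train"] * n, dtype=object)
        test_idx = rng.choice(n, size=test_counts[sex], replace=False)
        tags[test_idx] = "test"
        pixels.append(imgs)
        labels.extend([sex] * n)
        partition.extend(tags)

    return ImageSet(np.concatenate(pixels), np.array(labels), np.array(partition))


# ---------------------------------------------------------------------------
# on-disk formats: delimited text tables, 8-bit grayscale PNG + CSV manifest


def write_table(path: str, table: MorphometricTable) -> None:
    """Write a table as CSV: header, empty string for missing, final 'sex'."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*table.feature_names, "sex"])
        for i in range(table.n_rows):
            row = [
                "" if table.missing_mask[i, j] else repr(float(table.values[i, j]))
                for j in range(table.n_features)
            ]
            writer.writerow([*row, str(table.labels[i])])


def read_table(path: str) -> MorphometricTable:
    """Read the CSV table format; errors name the offending record."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, no header") from None
        if len(header) < 2 or header[-1] != "sex":
            raise FormatError(f"{path}: header must end with a 'sex' column")
        names = header[:-1]
        p = len(names)
        values, mask, labels = [], [], []
        for i, row in enumerate(reader):
            if len(row) != p + 1:
                raise FormatError(
                    f"{path}: row {i} has {len(row)} fields, header declares {p + 1}"
                )
            cells = []
            miss = []
            for j, cell in enumerate(row[:-1]):
                if cell == "":
                    cells.append(np.nan)
                    miss.append(True)
                else:
                    try:
                        cells.append(float(cell))
                    except ValueError:
                        raise FormatError(
                            f"{path}: row {i}, column {names[j]!r}: "
                            f"non-numeric value {cell!r}"
                        ) from None
                    miss.append(False)
            sex = row[-1]
            if sex not in (FEMALE, MALE):
                raise FormatError(f"{path}: row {i}: sex must be F or M, got {sex!r}")
            values.append(cells)
            mask.append(miss)
            labels.append(sex)
    if not values:
        raise FormatError(f"{path}: table has no data rows")
    return MorphometricTable(np.array(values), np.array(mask), np.array(labels), names)


def write_images(directory: str, imageset: ImageSet) -> None:
    """Write 8-bit grayscale PNGs plus a manifest.csv (filename,sex,partition)."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i in range(imageset.pixels.shape[0]):
        fname = f"img_{i:05d}.png"
        arr = np.clip(np.round(imageset.pixels[i] * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(os.path.join(directory, fname))
        rows.append((fname, str(imageset.labels[i]), str(imageset.partition[i])))
    with open(os.path.join(directory, "manifest.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "sex", "partition"])
        writer.writerows(rows)


def read_images(directory: str) -> ImageSet:
    """Read the PNG + manifest format written by :func:`write_images`."""
    manifest = os.path.join(directory, "manifest.csv")
    if not os.path.exists(manifest):
        raise FormatError(f"{directory}: manifest.csv not found")
    pixels, labels, partition = [], [], []
    with open(manifest, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["filename", "sex", "partition"]:
            raise FormatError(f"{manifest}: unexpected header {header}")
        for i, row in enumerate(reader):
            if len(row) != 3:
                raise FormatError(f"{manifest}: row {i} has {len(row)} fields")
            fname, sex, part = row
            if sex not in (FEMALE, MALE):
                raise FormatError(f"{manifest}: row {i}: bad sex {sex!r}")
            fpath = os.path.join(directory, fname)
            try:
                with Image.open(fpath) as im:
                    arr = np.asarray(im.convert("L"), dtype=float) / 255.0
            except OSError as exc:
                raise FormatError(f"{manifest}: row {i}: unreadable image "
                                  f"{fname!r} ({exc})") from None
            pixels.append(arr)
            labels.append(sex)
            partition.append(part)
    if not pixels:
        raise FormatError(f"{manifest}: no images listed")
    return ImageSet(np.stack(pixels), np.array(labels), np.array(partition))
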