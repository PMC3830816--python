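"""Reading, writing and synthesis of CTG-style feature tables.

A dataset is a numeric feature matrix (21 cardiotocogram summary features by
default) plus a three-valued fetal-state label. Real data arrives as
delimited text with an ``NSP``/``CLASS`` column coded 1/2/3; synthetic data
is drawn from a seeded spherical-Gaussian mixture with controllable class
imbalance and between-class separation.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DimensionError,
    EmptyDatasetError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: canonical feature names of the 21-feature CTG table
FEATURE_NAMES: tuple[str, ...] = (
    "LB", "AC", "FM", "UC", "DL", "DS", "DP",
    "ASTV", "MSTV", "ALTV", "MLTV",
    "Width", "Min", "Max", "N_max", "N_zeros",
    "Mode", "Mean", "Median", "Variance", "Tendency",
)

#: fetal-state class names in UCI NSP code order (1, 2, 3)
CLASS_NAMES: tuple[str, str, str] = ("normal", "suspect", "pathologic")

NSP_TO_CLASS = {1: "normal", 2: "suspect", 3: "pathologic"}
CLASS_TO_NSP = {v: k for k, v in NSP_TO_CLASS.items()}

LABEL_COLUMN_ALIASES = ("NSP", "CLASS")


def _canon(name: str) -> str:
    """Normalize a header token for case/underscore-insensitive matching."""
    return name.strip().upper().replace("_", "").replace(".", "")


@dataclass
class Dataset:
    """A feature table with class labels and provenance metadata."""

    X: np.ndarray                  # (n, p) float matrix
    y: np.ndarray                  # (n,) array of class-name strings
    feature_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValidationError("label vector length does not match rows")
        if self.X.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length does not match columns")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.feature_names))
        frame["state"] = self.y
        return frame


@dataclass(frozen=True)
class FeatureScaling:
    """Per-feature location/scale record for z-score standardization.

    Zero-variance features get scale 1 so they pass through unchanged.
    """

    mean: np.ndarray
    scale: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) / self.scale

    def invert(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaling":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float))


def standardize_fit(X: np.ndarray) -> FeatureScaling:
    """Fit per-feature z-score parameters on a training matrix."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValidationError("cannot standardize an empty matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0.0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) left unscaled",
            stacklevel=2,
        )
    scale = np.where(constant, 1.0, sd)
    return FeatureScaling(mean=mean, scale=scale)


def standardize_apply(stats: FeatureScaling, X: np.ndarray) -> np.ndarray:
    """Apply fitted z-score parameters to a matrix."""
    return stats.apply(X)


def read_ctg(path) -> Dataset:
    """Read a CTG feature table from delimited text (comma or semicolon).

    The header must contain the 21 canonical feature names
    (case/underscore-insensitive) and a label column named ``NSP`` or
    ``CLASS`` with values in {1, 2, 3}. Rows with missing, non-numeric or
    out-of-range values are rejected with their line numbers logged.
    """
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(4096)
    try:
        delimiter = csv.Sniffer().sniff(sample, delimiters=",;").delimiter
    except csv.Error:
        delimiter = ","

    table = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    canon_to_actual = {_canon(c): c for c in table.columns}

    missing = [f for f in FEATURE_NAMES if _canon(f) not in canon_to_actual]
    if missing:
        raise SchemaError(f"missing required feature column(s): {missing}")
    label_col = next(
        (canon_to_actual[_canon(a)] for a in LABEL_COLUMN_ALIASES
         if _canon(a) in canon_to_actual),
        None,
    )
    if label_col is None:
        raise SchemaError("missing label column (expected 'NSP' or 'CLASS')")

    feature_cols = [canon_to_actual[_canon(f)] for f in FEATURE_NAMES]
    values = table[feature_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    codes = pd.to_numeric(table[label_col], errors="coerce").to_numpy()

    bad_features = ~np.isfinite(values).all(axis=1)
    bad_labels = ~np.isin(codes, list(NSP_TO_CLASS))
    bad = bad_features | bad_labels
    for row in np.flatnonzero(bad):
        # +2: header line plus 1-based numbering
        logger.warning("rejected line %d of %s (invalid feature or label)",
                       row + 2, path)
    if bad.all():
        raise EmptyDatasetError(f"no valid rows in {path}")

    keep = ~bad
    y = np.array([NSP_TO_CLASS[int(c)] for c in codes[keep]], dtype=object)
    return Dataset(
        X=values[keep],
        y=y,
        feature_names=FEATURE_NAMES,
        provenance={"read": str(path), "rejected_rows": int(bad.sum())},
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic three-class Gaussian-mixture generator.

    Default class sizes mirror the 1655:295:176 CTG imbalance at one-fifth
    scale. Class means are spaced ``separation * within_class_sd`` apart
    along distinct coordinate axes unless explicit means are given.
    """

    n_per_class: tuple[int, ...] = (331, 59, 35)
    dim: int = 21
    class_means: Sequence[np.ndarray] | None = None
    within_class_sd: float = 1.0
    separation: float = 4.0
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        if self.separation <= 0:
            raise ValidationError("separation must be positive")
        if self.within_class_sd <= 0:
            raise ValidationError("within_class_sd must be positive")
        if len(self.n_per_class) != len(self.class_names):
            raise ValidationError("n_per_class must match class_names length")
        if any(n < 2 for n in self.n_per_class):
            raise ValidationError("each class needs at least 2 points")
        if self.class_means is not None:
            if len(self.class_means) != len(self.class_names):
                raise ValidationError("class_means must match class count")
        elif len(self.class_names) > self.dim:
            raise ValidationError("dim must be >= number of classes for "
                                  "axis-aligned default means")


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw a seeded spherical-Gaussian mixture dataset per the spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.class_means is not None:
        means = [np.asarray(m, dtype=float) for m in spec.class_means]
    else:
        gap = spec.separation * spec.within_class_sd
        means = []
        for c in range(len(spec.class_names)):
            m = np.zeros(spec.dim)
            m[c] = gap
            means.append(m)

    blocks, labels = [], []
    for name, n, mu in zip(spec.class_names, spec.n_per_class, means):
        blocks.append(rng.normal(loc=mu, scale=spec.within_class_sd,
                                 size=(n, spec.dim)))
        labels.extend([name] * n)

    names = (FEATURE_NAMES if spec.dim == len(FEATURE_NAMES)
             else tuple(f"f{i+1}" for i in range(spec.dim)))
    provenance = {
        "synthetic": {
            "n_per_class": list(spec.n_per_class),
            "dim": spec.dim,
            "within_class_sd": spec.within_class_sd,
            "separation": spec.separation,
            "seed": spec.seed,
        }
    }
    return Dataset(X=np.vstack(blocks), y=np.array(labels, dtype=object),
                   feature_names=names, provenance=provenance)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as CSV with an NSP label column (when CTG-labelled)."""
    frame = pd.DataFrame(dataset.X, columns=list(dataset.feature_names))
    if set(np.unique(dataset.y.astype(str))) <= set(CLASS_NAMES):
        frame["NSP"] = [CLASS_TO_NSP[str(s)] for s in dataset.y]
    else:
        frame["state"] = dataset.y
    frame.to_csv(path, index=False)


def write_predictions(dataset: Dataset, predicted: Sequence[str], path) -> None:
    """Write the original columns plus a ``predicted_state`` column as CSV."""
    predicted = np.asarray(predicted, dtype=object)
    if len(predicted) != len(dataset):
        raise DimensionError(
            f"{len(predicted)} predictions for {len(dataset)} rows")
    frame = dataset.to_frame()
    frame["predicted_state"] = predicted
    frame.to_csv(path, index=False)
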