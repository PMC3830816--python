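"""Cross-validation and multiclass performance evaluation.

Confusion matrices here follow the medical-reporting layout: rows are the
predicted class, columns the actual class, so each column sums to the
actual per-class count. Column-normalizing gives the confusion ratio
matrix whose diagonal is per-class recall and whose off-diagonal cells are
misclassification rates; those off-diagonals feed the cobweb (radar)
representation, compared against the chance polygon at 1/R per axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import pso, tree as tree_mod
from .data import Dataset
from .exceptions import (
    DomainError,
    NormalizationError,
    UndefinedRateError,
    ValidationError,
)
from .folds import FoldAssignment, stratified_kfold  # noqa: F401  (public API)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """R x R counts; rows = predicted class, columns = actual class."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts)
        r = len(self.class_order)
        if counts.shape != (r, r):
            raise ValidationError(f"counts must be {r}x{r}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_labels(cls, actual, predicted, class_order) -> "ConfusionMatrix":
        actual = np.asarray(actual, dtype=object).astype(str)
        predicted = np.asarray(predicted, dtype=object).astype(str)
        if actual.shape != predicted.shape:
            raise ValidationError("actual/predicted length mismatch")
        order = tuple(class_order)
        index = {c: i for i, c in enumerate(order)}
        counts = np.zeros((len(order), len(order)), dtype=int)
        for a, p in zip(actual, predicted):
            counts[index[p], index[a]] += 1
        return cls(counts=counts, class_order=order)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ConfusionRatioMatrix:
    """Column-normalized confusion matrix; every column sums to 1."""

    ratios: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self):
        ratios = np.asarray(self.ratios, dtype=float)
        r = len(self.class_order)
        if ratios.shape != (r, r):
            raise ValidationError(f"ratios must be {r}x{r}")
        if np.any(ratios < 0) or np.any(ratios > 1):
            raise ValidationError("ratios must lie in [0, 1]")
        object.__setattr__(self, "ratios", ratios)

    def rounded(self, decimals: int = 3) -> np.ndarray:
        """Display form (internal values are kept at full precision)."""
        return np.round(self.ratios, decimals)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified points: trace / total."""
    if cm.total == 0:
        raise DomainError("confusion matrix is empty")
    return float(np.trace(cm.counts)) / cm.total


def column_normalize(cm: ConfusionMatrix) -> ConfusionRatioMatrix:
    """Divide each column by its actual-class total."""
    totals = cm.column_totals()
    for cls, t in zip(cm.class_order, totals):
        if t == 0:
            raise NormalizationError(
                f"actual class {cls!r} has no data points")
    return ConfusionRatioMatrix(ratios=cm.counts / totals[np.newaxis, :],
                                class_order=cm.class_order)


def sensitivity_specificity(cm2: ConfusionMatrix) -> tuple[float, float]:
    """TP/(TP+FN) and TN/(TN+FP) of a 2x2 matrix (positive class first)."""
    if len(cm2.class_order) != 2:
        raise ValidationError("sensitivity/specificity need a 2x2 matrix")
    tp, fp = int(cm2.counts[0, 0]), int(cm2.counts[0, 1])
    fn, tn = int(cm2.counts[1, 0]), int(cm2.counts[1, 1])
    if tp + fn == 0:
        raise UndefinedRateError("sensitivity undefined: TP+FN is zero")
    if tn + fp == 0:
        raise UndefinedRateError("specificity undefined: TN+FP is zero")
    return tp / (tp + fn), tn / (tn + fp)


def one_vs_rest(cm: ConfusionMatrix, positive: str) -> ConfusionMatrix:
    """Collapse an R-class matrix to 2x2 with ``positive`` against the rest."""
    if positive not in cm.class_order:
        raise ValidationError(f"unknown class {positive!r}")
    i = cm.class_order.index(positive)
    tp = cm.counts[i, i]
    fp = cm.counts[i, :].sum() - tp
    fn = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fp - fn
    return ConfusionMatrix(
        counts=np.array([[tp, fp], [fn, tn]], dtype=int),
        class_order=(positive, f"not-{positive}"),
    )


@dataclass(frozen=True)
class CobwebPolygon:
    """The R^2 - R off-diagonal misclassification rates on radar axes.

    Axes are ordered column-major: by actual class, then by predicted class
    within the column, both in ``class_order``. The chance classifier sits
    at 1/R on every axis.
    """

    axes: tuple[tuple[str, str], ...]   # (predicted, actual) pairs
    values: np.ndarray
    chance_value: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if len(values) != len(self.axes):
            raise ValidationError("axis/value length mismatch")
        if np.any(values < 0) or np.any(values > 1):
            raise ValidationError("misclassification rates must be in [0, 1]")
        object.__setattr__(self, "values", values)

    def within_chance(self) -> bool:
        return bool(np.all(self.values < self.chance_value))


def cobweb_coordinates(crm: ConfusionRatioMatrix) -> CobwebPolygon:
    """Extract the off-diagonal rates of a ratio matrix onto cobweb axes."""
    order = crm.class_order
    r = len(order)
    axes, values = [], []
    for j, actual in enumerate(order):
        for i, predicted in enumerate(order):
            if i == j:
                continue
            axes.append((predicted, actual))
            values.append(crm.ratios[i, j])
    return CobwebPolygon(axes=tuple(axes), values=np.array(values),
                         chance_value=1.0 / r)


def chance_ratio_matrix(class_order) -> ConfusionRatioMatrix:
    """The ratio matrix of a chance classifier: every entry 1/R."""
    order = tuple(class_order)
    r = len(order)
    return ConfusionRatioMatrix(ratios=np.full((r, r), 1.0 / r),
                                class_order=order)


def render_cobweb(polygon: CobwebPolygon, path, title: str | None = None):
    """Save a radar plot of the polygon with the chance polygon overlaid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(polygon.axes)
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    # start at the top, proceed clockwise
    angles = np.pi / 2.0 - angles

    def close(vals):
        return np.concatenate([vals, vals[:1]])

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(6, 6))
    ax.plot(close(angles), close(np.full(n, polygon.chance_value)),
            "k--", label=f"chance (1/R = {polygon.chance_value:.2f})")
    ax.plot(close(angles), close(polygon.values), "o-",
            label="classifier")
    ax.fill(close(angles), close(polygon.values), alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels([f"predicted-as-{p} | actual-{a}"
                        for p, a in polygon.axes], fontsize=7)
    ax.set_ylim(0, min(1.0, max(float(polygon.values.max()) * 1.2,
                                polygon.chance_value * 1.5)))
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", bbox_to_anchor=(1.1, -0.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


@dataclass
class CVResult:
    """Outcome of a k-fold cross-validation run."""

    fold_accuracies: list[float]
    confusion: ConfusionMatrix
    fold_hyperparameters: list[list[dict]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        """Headline metric: arithmetic mean of the per-fold accuracies."""
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        """Accuracy of the pooled confusion matrix; differs from the fold
        mean when folds are unequal in size."""
        return overall_accuracy(self.confusion)


def cross_validate(data: Dataset, plan: tree_mod.ClassPartitionPlan,
                   swarm_config: pso.SwarmConfig, k: int, seed: int,
                   scale: bool = True,
                   inner_cv_folds: int = 5) -> CVResult:
    """Stratified k-fold CV of the full nested pipeline.

    Each fold fits a fresh tree (with per-fold PSO seeds derived from
    ``seed``) on the training union and scores the held-out fold; all
    held-out predictions are pooled into one confusion matrix.
    """
    y = data.y.astype(str)
    folds = stratified_kfold(y, k, seed)
    class_order = plan.classes

    fold_accuracies: list[float] = []
    fold_hypers: list[list[dict]] = []
    actual_all: list[np.ndarray] = []
    predicted_all: list[np.ndarray] = []
    for f in range(1, k + 1):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        fold_seed = int(np.random.SeedSequence(
            [seed, f]).generate_state(1)[0])
        train_data = Dataset(X=data.X[tr], y=y[tr],
                             feature_names=data.feature_names,
                             provenance=data.provenance)
        fitted = tree_mod.fit_tree(
            train_data, plan, pso.with_seed(swarm_config, fold_seed),
            scale=scale, inner_cv_folds=inner_cv_folds)
        predicted = tree_mod.predict_tree(fitted, data.X[te])
        acc = float(np.mean(predicted.astype(str) == y[te]))
        fold_accuracies.append(acc)
        fold_hypers.append([
            {"gamma": m.hyper.gamma, "sigma2": m.hyper.sigma2}
            for m in fitted.node_models
        ])
        for node, h in enumerate(fold_hypers[-1], start=1):
            logger.info("fold %d node %d: gamma=%.4g sigma2=%.4g",
                        f, node, h["gamma"], h["sigma2"])
        actual_all.append(y[te])
        predicted_all.append(predicted.astype(str))
        logger.info("fold %d accuracy %.4f (%d test points)", f, acc,
                    len(te))

    confusion = ConfusionMatrix.from_labels(
        np.concatenate(actual_all), np.concatenate(predicted_all),
        class_order)
    return CVResult(fold_accuracies=fold_accuracies, confusion=confusion,
                    fold_hyperparameters=fold_hypers)
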