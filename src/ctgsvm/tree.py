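"""Multiclass classification via a binary tree of LS-SVM node classifiers.

R classes are split by R-1 binary classifiers arranged in a tree: each
internal node separates its class set into a positive and a negative subset,
and a query is routed from the root until a single class remains. The fixed
three-class fetal-state tree puts {pathologic, suspect} against {normal} at
the root (erring away from missing an abnormal case), then pathologic
against suspect below.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import lssvm, pso
from .data import CLASS_NAMES, CLASS_TO_NSP, Dataset
from .exceptions import DegenerateInputError, DimensionError, PlanError

logger = logging.getLogger(__name__)

TREE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Split:
    """One internal node: parent class set divided into positive/negative."""

    parent: tuple[str, ...]
    positive: tuple[str, ...]
    negative: tuple[str, ...]


@dataclass(frozen=True)
class ClassPartitionPlan:
    """An ordered list of splits forming a binary tree over R classes.

    Exactly R-1 splits; every split's positive and negative subsets are
    disjoint, non-empty and union to the parent; leaves are the R
    singleton classes.
    """

    classes: tuple[str, ...]
    splits: tuple[Split, ...]

    def __post_init__(self):
        r = len(self.classes)
        if r < 2:
            raise PlanError("a plan needs at least 2 classes")
        if len(set(self.classes)) != r:
            raise PlanError("duplicate class names")
        if len(self.splits) != r - 1:
            raise PlanError(
                f"{r} classes require exactly {r - 1} splits, "
                f"got {len(self.splits)}")

        pending = {frozenset(self.classes)}
        for s in self.splits:
            parent = frozenset(s.parent)
            pos, neg = frozenset(s.positive), frozenset(s.negative)
            if parent not in pending:
                raise PlanError(f"split parent {sorted(parent)} is not an "
                                "open subtree")
            if not pos or not neg:
                raise PlanError("positive and negative subsets must be "
                                "non-empty")
            if pos & neg:
                raise PlanError(f"overlapping subsets in split of "
                                f"{sorted(parent)}")
            if pos | neg != parent:
                raise PlanError(f"subsets of {sorted(parent)} do not union "
                                "to the parent")
            pending.remove(parent)
            for child in (pos, neg):
                if len(child) > 1:
                    pending.add(child)
        if pending:
            raise PlanError(f"unsplit non-singleton subsets remain: "
                            f"{[sorted(p) for p in pending]}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def split_for(self, class_set: frozenset[str]) -> int:
        for i, s in enumerate(self.splits):
            if frozenset(s.parent) == class_set:
                return i
        raise PlanError(f"no split for class set {sorted(class_set)}")


def ctg_plan() -> ClassPartitionPlan:
    """The fixed fetal-state tree: root {pathologic, suspect} vs {normal},
    then {pathologic} vs {suspect}."""
    return ClassPartitionPlan(
        classes=CLASS_NAMES,
        splits=(
            Split(parent=CLASS_NAMES,
                  positive=("pathologic", "suspect"),
                  negative=("normal",)),
            Split(parent=("pathologic", "suspect"),
                  positive=("pathologic",),
                  negative=("suspect",)),
        ),
    )


def build_generic_plan(classes, splits) -> ClassPartitionPlan:
    """Validate a user-supplied split sequence into a plan.

    ``splits`` is an iterable of (parent, positive, negative) class-name
    sequences or :class:`Split` objects.
    """
    normalized = tuple(
        s if isinstance(s, Split)
        else Split(parent=tuple(s[0]), positive=tuple(s[1]),
                   negative=tuple(s[2]))
        for s in splits
    )
    return ClassPartitionPlan(classes=tuple(classes), splits=normalized)


@dataclass
class BDTree:
    """A fitted tree: the plan, one LS-SVM per split, and tuning traces."""

    plan: ClassPartitionPlan
    node_models: list[lssvm.LSSVMModel]
    node_traces: list[list[float]] = field(default_factory=list)
    class_codes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.node_models) != self.plan.n_classes - 1:
            raise PlanError(f"{self.plan.n_classes} classes require "
                            f"{self.plan.n_classes - 1} node models")
        if not self.class_codes:
            self.class_codes = {c: CLASS_TO_NSP.get(c, i + 1)
                                for i, c in enumerate(self.plan.classes)}

    @property
    def n_features(self) -> int:
        return self.node_models[0].n_features

    def to_dict(self) -> dict:
        return {
            "format_version": TREE_FORMAT_VERSION,
            "classes": list(self.plan.classes),
            "splits": [
                {"parent": list(s.parent), "positive": list(s.positive),
                 "negative": list(s.negative)}
                for s in self.plan.splits
            ],
            "node_models": [m.to_dict() for m in self.node_models],
            "node_traces": [list(t) for t in self.node_traces],
            "class_codes": self.class_codes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BDTree":
        plan = build_generic_plan(
            d["classes"],
            [(s["parent"], s["positive"], s["negative"]) for s in d["splits"]],
        )
        return cls(
            plan=plan,
            node_models=[lssvm.LSSVMModel.from_dict(m)
                         for m in d["node_models"]],
            node_traces=[list(t) for t in d.get("node_traces", [])],
            class_codes={k: int(v) for k, v in d["class_codes"].items()},
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "BDTree":
        return cls.from_dict(json.loads(text))


def fit_tree(data: Dataset, plan: ClassPartitionPlan,
             swarm_config: pso.SwarmConfig, scale: bool = True,
             inner_cv_folds: int = 5) -> BDTree:
    """Train one PSO-tuned LS-SVM per split on its parent's data points.

    Each node sees only rows whose class belongs to the split's parent set,
    recoded +1 for the positive subset. Hyperparameters are tuned per node
    with a node-specific PSO seed derived from the swarm config seed.
    """
    y = data.y.astype(str)
    for cls in plan.classes:
        n = int(np.sum(y == cls))
        if n < 2:
            raise DegenerateInputError(
                f"class {cls!r} has {n} data point(s); need at least 2")

    models, traces = [], []
    for i, split_ in enumerate(plan.splits):
        mask = np.isin(y, split_.parent)
        X_node = data.X[mask]
        y_node = np.where(np.isin(y[mask], split_.positive), 1.0, -1.0)
        node_seed = int(np.random.SeedSequence(
            [swarm_config.seed, i]).generate_state(1)[0])
        node_config = pso.with_seed(swarm_config, node_seed)
        hyper, trace = pso.tune_hyperparameters(
            X_node, y_node, node_config, inner_cv_folds=inner_cv_folds,
            scale=scale)
        logger.info("node %d (%s vs %s): gamma=%.4g sigma2=%.4g on %d points",
                    i + 1, "+".join(split_.positive),
                    "+".join(split_.negative), hyper.gamma, hyper.sigma2,
                    len(X_node))
        models.append(lssvm.fit(X_node, y_node, hyper, scale=scale))
        traces.append(trace)
    return BDTree(plan=plan, node_models=models, node_traces=traces)


def predict_tree(tree: BDTree, X: np.ndarray) -> np.ndarray:
    """Route queries down the tree; returns class-name labels."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != tree.n_features:
        raise DimensionError(f"query has {X.shape[1]} features, tree "
                             f"expects {tree.n_features}")
    out = np.empty(X.shape[0], dtype=object)

    def route(indices: np.ndarray, class_set: frozenset[str]) -> None:
        if len(class_set) == 1:
            out[indices] = next(iter(class_set))
            return
        if indices.size == 0:
            return
        i = tree.plan.split_for(class_set)
        split_ = tree.plan.splits[i]
        signs = lssvm.predict(tree.node_models[i], X[indices])
        route(indices[signs > 0], frozenset(split_.positive))
        route(indices[signs < 0], frozenset(split_.negative))

    route(np.arange(X.shape[0]), frozenset(tree.plan.classes))
    return out
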