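"""Seeded stratified k-fold assignment.

Lives in its own module so both the optimizer (inner tuning folds) and the
evaluation layer (outer folds) can use it without an import cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import StratificationError


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index in [1, k] for every data point."""

    k: int
    fold_index: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def stratified_kfold(labels, k: int, seed: int) -> FoldAssignment:
    """Assign each point to one of k folds, preserving class proportions.

    Within each class the points are shuffled with the seeded generator and
    dealt round-robin to folds, so per-class fold counts differ by at most
    one. Classes smaller than k raise :class:`StratificationError`.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise StratificationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    fold_index = np.zeros(len(labels), dtype=int)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < k:
            raise StratificationError(
                f"class {cls!r} has {len(members)} members, fewer than k={k}")
        rng.shuffle(members)
        fold_index[members] = np.arange(len(members)) % k + 1
    return FoldAssignment(k=k, fold_index=fold_index, seed=seed)
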