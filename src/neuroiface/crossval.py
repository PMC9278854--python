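"""Cross-validation fold plans.

Stratified k-fold allocation spreads each stratum (class label, or object
id when stratification is at the object level) as evenly across folds as
the counts allow; strata smaller than k are dealt round-robin after a
seeded shuffle rather than raising.  Leave-one-class-out yields one fold
per class containing the entirety of that class, for zero-shot evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream

STRATIFIED = "stratified_kfold"
LOCO = "leave_one_class_out"


@dataclass
class FoldPlan:
    """k folds of held-out row indices partitioning all rows."""

    folds: list[np.ndarray]
    scheme: str = STRATIFIED
    strat_key: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = sum(len(f) for f in self.folds)
        allrows = np.concatenate([np.asarray(f) for f in self.folds]) if self.folds else np.array([])
        if len(np.unique(allrows)) != n:
            raise ValueError("folds must partition rows without overlap")
        self.n = n

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_rows(self, fold: int) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.folds[fold]] = False
        return np.flatnonzero(mask)


def make_fold_plan(strat_key: np.ndarray, k: int = 8, scheme: str = STRATIFIED,
                   seed: int = 0) -> FoldPlan:
    """Build a fold plan over ``strat_key`` (class labels or object ids)."""
    strat_key = np.asarray(strat_key)
    n = strat_key.size
    if scheme == LOCO:
        classes = np.unique(strat_key)
        folds = [np.flatnonzero(strat_key == c) for c in classes]
        return FoldPlan(folds, scheme=LOCO, strat_key=strat_key)
    if scheme != STRATIFIED:
        raise ValueError(f"unknown scheme {scheme!r}")
    if k < 2:
        raise ValueError("stratified k-fold needs k >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} rows")
    rng = substream(seed, "folds")
    folds: list[list[int]] = [[] for _ in range(k)]
    pointer = 0
    classes = np.unique(strat_key)
    for c in classes:
        rows = np.flatnonzero(strat_key == c)
        rng.shuffle(rows)
        # round-robin deal with a persistent pointer: exact 1/k allocation when
        # counts divide k, and a globally balanced deal for small strata
        for r in rows:
            folds[pointer % k].append(int(r))
            pointer += 1
    return FoldPlan([np.sort(np.array(f, dtype=int)) for f in folds],
                    scheme=STRATIFIED, strat_key=strat_key)
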