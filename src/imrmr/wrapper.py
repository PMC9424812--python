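"""Wrapper stage: flatten the subset sequence into a feature sequence, run
sequential forward search (feature-wise SFS or subset-wise SFSFs) under a
pluggable classifier, and sweep the α/β grid for the final subset CS*.

SFS here is prefix evaluation along the subset-search ordering: the ranking
stage has already decided the order, and the wrapper evaluates the nested
prefixes order[:k] for k = 1..M, returning the accuracy-maximizing prefix
(ties → shortest). SFSFs adds whole subsets in sequence order and stops at
the first cumulative set whose accuracy reaches the all-features baseline;
if none does, the best cumulative set seen is returned and flagged as
non-converged.

Two model-selection protocols are provided. The default, ``cv``, scores a
candidate feature set by stratified k-fold cross-validated accuracy on the
training split only, so the held-out test side never influences selection.
``paper_faithful`` fits on the training split and scores on the held-out
side — the protocol the published tables imply, which leaks the test set
into model selection; it is kept for comparability and flagged as such.
Accuracies are percentages in [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .datasets import FeatureTable, SplitPair, stratified_split
from .grouping import make_plan
from .ranking import PairwiseStats, SubsetSequence, rank_subsets
from .relevance import DiscretizationScheme, relevance_profile

logger = logging.getLogger(__name__)

Evaluator = Callable[[tuple[int, ...]], float]


def default_classifier(seed: int = 0, n_estimators: int = 100) -> RandomForestClassifier:
    """The reference wrapper classifier: a seeded random forest."""
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def flatten_sequence(seq: SubsetSequence) -> list[int]:
    """Concatenate subset members in sequence order into a feature list."""
    return [f for s in seq.ordered for f in s.subset.members]


def make_evaluator(
    split: SplitPair,
    estimator,
    protocol: str = "cv",
    cv: int = 5,
    seed: int = 0,
) -> Evaluator:
    """Build a memoized feature-set → accuracy-% scorer.

    ``cv``: mean stratified k-fold accuracy on the training split.
    ``paper_faithful``: fit on train, score on the held-out test split.
    """
    if protocol not in ("cv", "paper_faithful"):
        raise ValueError(f"unknown protocol {protocol!r}")
    cache: dict[tuple[int, ...], float] = {}
    y_train = split.train.class_codes
    y_test = split.test.class_codes

    def evaluate(features: tuple[int, ...]) -> float:
        features = tuple(int(f) for f in features)
        if features in cache:
            return cache[features]
        clf = clone(estimator)
        if "random_state" in clf.get_params():
            clf.set_params(random_state=seed)
        X_train = split.train.X[:, list(features)]
        if protocol == "cv":
            n_splits = min(cv, int(np.bincount(y_train).min()))
            n_splits = max(n_splits, 2)
            folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            acc = float(cross_val_score(clf, X_train, y_train, cv=folds, scoring="accuracy").mean())
        else:
            clf.fit(X_train, y_train)
            acc = float(np.mean(clf.predict(split.test.X[:, list(features)]) == y_test))
        cache[features] = 100.0 * acc
        return cache[features]

    return evaluate


def sfs_select(
    order: Sequence[int], evaluate: Evaluator
) -> tuple[tuple[int, ...], float, list[float]]:
    """Evaluate every prefix of ``order`` and keep the accuracy-maximizing
    one; ties go to the shortest prefix. Returns (features, accuracy,
    accuracy after each inclusion step)."""
    order = [int(f) for f in order]
    if len(set(order)) != len(order):
        raise ValueError("feature order contains duplicates")
    if not order:
        raise ValueError("empty feature order")
    path: list[float] = []
    best_k, best_acc = 1, -np.inf
    for k in range(1, len(order) + 1):
        acc = evaluate(tuple(order[:k]))
        path.append(acc)
        if acc > best_acc:
            best_k, best_acc = k, acc
    return tuple(order[:best_k]), best_acc, path


def sfsfs_select(
    seq: SubsetSequence,
    evaluate: Evaluator,
    raw_accuracy: float,
) -> tuple[tuple[int, ...], float, list[float], bool]:
    """Subset-wise forward selection: starting from the empty set, add whole
    subsets in sequence order until the cumulative accuracy reaches
    ``raw_accuracy`` (the all-features baseline under the same protocol).
    If it never does, return the best cumulative set seen, flagged
    non-converged. Returns (features, accuracy, path, converged)."""
    features: list[int] = []
    path: list[float] = []
    best: tuple[int, ...] = ()
    best_acc = -np.inf
    for score in seq.ordered:
        features.extend(score.subset.members)
        acc = evaluate(tuple(features))
        path.append(acc)
        if acc > best_acc:
            best, best_acc = tuple(features), acc
        if acc >= raw_accuracy:
            return tuple(features), acc, path, True
    logger.warning(
        "SFSFs did not reach the raw accuracy %.2f%%; returning best cumulative subset "
        "(%d features, %.2f%%)", raw_accuracy, len(best), best_acc,
    )
    return best, best_acc, path, False


@dataclass(frozen=True)
class GridCell:
    """One evaluated (α, β) grid point."""

    alpha: float
    beta: float
    features: tuple[int, ...]
    accuracy: float
    accuracy_path: tuple[float, ...]
    converged: bool = True


@dataclass(frozen=True)
class SelectionResult:
    """Final selection: CS*, the winning (α, β), and the full grid record."""

    features: tuple[int, ...]
    alpha: float
    beta: float
    accuracy: float
    accuracy_path: tuple[float, ...]
    mode: str
    converged: bool
    grid: tuple[GridCell, ...]
    b_max_per_alpha: dict[float, GridCell] = field(default_factory=dict)

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        d = {
            "features": list(self.features),
            "alpha": self.alpha,
            "beta": self.beta,
            "accuracy": self.accuracy,
            "accuracy_path": list(self.accuracy_path),
            "mode": self.mode,
            "converged": self.converged,
            "n_selected": len(self.features),
            "grid": [
                {
                    "alpha": c.alpha,
                    "beta": c.beta,
                    "n_selected": len(c.features),
                    "accuracy": c.accuracy,
                    "converged": c.converged,
                    "features": list(c.features),
                }
                for c in self.grid
            ],
            "b_max_per_alpha": {
                str(a): {"beta": c.beta, "accuracy": c.accuracy, "features": list(c.features)}
                for a, c in self.b_max_per_alpha.items()
            },
        }
        if feature_names is not None:
            d["feature_names"] = [feature_names[i] for i in self.features]
        return d


def _cell_key(cell: GridCell) -> tuple:
    # highest accuracy, then shortest subset, then lexicographic (alpha, beta)
    return (-cell.accuracy, len(cell.features), cell.alpha, cell.beta)


DEFAULT_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))


def grid_select(
    table: FeatureTable,
    alphas: Sequence[float] = DEFAULT_GRID,
    betas: Sequence[float] = DEFAULT_GRID,
    estimator=None,
    mode: str = "sfs",
    scheme: DiscretizationScheme | None = None,
    seed: int = 0,
    protocol: str = "cv",
    cv: int = 5,
    grouping: str = "egm",
    train_fraction: float = 0.7,
    stratify: bool = True,
    split: SplitPair | None = None,
    normalize_subset_sums: bool = False,
) -> SelectionResult:
    """Sweep the (α, β) grid and return the final optimal subset CS*.

    For each α the features are relevance-ranked and grouped once; for each
    β the subsets are ordered by the incremental criterion and the wrapper
    (SFS prefix search or SFSFs) is run. The best β per α gives b_max(α),
    and the best of those over α gives CS*. Ties break to the shortest
    subset, then the lexicographically smallest (α, β). Deterministic given
    ``seed``.
    """
    if mode not in ("sfs", "sfsfs"):
        raise ValueError(f"unknown mode {mode!r}")
    estimator = estimator if estimator is not None else default_classifier(seed)
    if split is None:
        split = stratified_split(table, train_fraction, seed=seed, stratify=stratify)
    evaluate = make_evaluator(split, estimator, protocol=protocol, cv=cv, seed=seed)
    stats = PairwiseStats(split.train, scheme)
    m = split.train.n_features
    raw_accuracy = evaluate(tuple(range(m))) if mode == "sfsfs" else None

    cells: list[GridCell] = []
    b_max: dict[float, GridCell] = {}
    for alpha in alphas:
        profile = relevance_profile(split.train, alpha, stats.scheme, codes=stats.codes)
        plan = make_plan(profile.ranking, strategy=grouping, seed=seed)
        for beta in betas:
            seq = rank_subsets(
                plan, split.train, alpha, beta, stats=stats, profile=profile,
                normalize_subset_sums=normalize_subset_sums,
            )
            if mode == "sfs":
                feats, acc, path = sfs_select(flatten_sequence(seq), evaluate)
                converged = True
            else:
                feats, acc, path, converged = sfsfs_select(seq, evaluate, raw_accuracy)
            cell = GridCell(
                alpha=alpha, beta=beta, features=feats, accuracy=acc,
                accuracy_path=tuple(path), converged=converged,
            )
            cells.append(cell)
            logger.info(
                "grid cell alpha=%.1f beta=%.1f: %d features, accuracy %.2f%%",
                alpha, beta, len(feats), acc,
            )
            if alpha not in b_max or _cell_key(cell) < _cell_key(b_max[alpha]):
                b_max[alpha] = cell

    winner = min(cells, key=_cell_key)
    return SelectionResult(
        features=winner.features,
        alpha=winner.alpha,
        beta=winner.beta,
        accuracy=winner.accuracy,
        accuracy_path=winner.accuracy_path,
        mode=mode,
        converged=winner.converged,
        grid=tuple(cells),
        b_max_per_alpha=b_max,
    )
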