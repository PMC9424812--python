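"""Evaluation metrics and the repeated hold-out protocol.

Metrics follow the usual conventions, reported as percentages: accuracy
(correct / total), the dimensionality-reduction rate Dr = (1 − Sc/Oc)·100
for Sc selected of Oc original features, and the comprehensive rate
Z = θ·Acc + (1 − θ)·Dr that trades accuracy off against dimensionality
reduction (θ = 0.5 by default). Precision, recall and F-measure are
computed per class from the confusion matrix (0/0 → 0) and macro-averaged;
weighted averaging is available by flag. The evaluation protocol repeats a
stratified 7:3 split, runs the selector on the training side only, scores
on the test side, and reports arithmetic means over the repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as sk_confusion_matrix

from .datasets import FeatureTable, stratified_split
from .wrapper import default_classifier

logger = logging.getLogger(__name__)


def confusion(y_true: Sequence, y_pred: Sequence, labels: Sequence) -> np.ndarray:
    """K×K confusion matrix with rows = true class, columns = predicted."""
    return sk_confusion_matrix(list(y_true), list(y_pred), labels=list(labels))


def accuracy(cm: np.ndarray) -> float:
    """Percentage of correctly identified samples: 100 · trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm)) / float(total)


def dimensionality_reduction(sc: int, oc: int) -> float:
    """Dr = (1 − Sc/Oc) · 100 for Sc selected of Oc original features."""
    if not (1 <= sc <= oc):
        raise ValueError(f"need 1 <= Sc <= Oc, got Sc={sc}, Oc={oc}")
    return (1.0 - sc / oc) * 100.0


def comprehensive_rate(acc: float, dr: float, theta: float = 0.5) -> float:
    """Z = θ·Acc + (1 − θ)·Dr, the accuracy / dimensionality tradeoff."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    return theta * acc + (1.0 - theta) * dr


def precision_recall_f(cm: np.ndarray, average: str = "macro") -> tuple[float, float, float]:
    """Per-class precision/recall/F from the confusion matrix, averaged.

    P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R); 0/0 conventions give 0
    (a class never predicted contributes precision 0, logged). ``average``
    is 'macro' (unweighted class mean) or 'weighted' (by class support).
    Returned as percentages.
    """
    cm = np.asarray(cm, dtype=float)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    never_predicted = np.flatnonzero(cm.sum(axis=0) == 0)
    if never_predicted.size:
        logger.debug("classes never predicted (precision 0 by convention): %s", never_predicted)
    if average == "macro":
        w = np.full(cm.shape[0], 1.0 / cm.shape[0])
    elif average == "weighted":
        support = cm.sum(axis=1)
        w = support / support.sum()
    else:
        raise ValueError(f"unknown average {average!r}")
    return 100.0 * float(p @ w), 100.0 * float(r @ w), 100.0 * float(f @ w)


@dataclass(frozen=True)
class EvalReport:
    """Aggregated repeated hold-out results (means over repeats, %)."""

    acc: float
    dr: float
    z: float
    precision: float
    recall: float
    f_measure: float
    sc: float
    oc: int
    n_repeats: int
    theta: float
    per_repeat: tuple[dict, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "dr": self.dr,
            "z": self.z,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "mean_selected": self.sc,
            "n_original": self.oc,
            "n_repeats": self.n_repeats,
            "theta": self.theta,
            "per_repeat": list(self.per_repeat),
        }

    def to_tsv_row(self, name: str = "") -> str:
        return "\t".join(
            [name]
            + [f"{v:.2f}" for v in (self.acc, self.dr, self.z, self.precision, self.recall, self.f_measure)]
        )


Selector = Callable[[FeatureTable, int], Sequence[int]]


def repeated_evaluation(
    table: FeatureTable,
    selector: Selector,
    repeats: int = 30,
    seed: int = 0,
    estimator=None,
    train_fraction: float = 0.7,
    theta: float = 0.5,
    average: str = "macro",
    stratify: bool = True,
) -> EvalReport:
    """Repeat the hold-out protocol: fresh stratified split per repeat
    (seed + i), selector applied to the training side only, final classifier
    fit on the selected training columns and scored on the test side.

    ``selector(train_table, seed)`` returns the selected feature indices.
    Means over repeats are reported; Z is recomputed from the mean Acc and
    mean Dr, which equals the mean of per-repeat Z by linearity.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    estimator = estimator if estimator is not None else default_classifier(seed)
    oc = table.n_features
    records: list[dict] = []
    for i in range(repeats):
        rep_seed = seed + i
        try:
            split = stratified_split(table, train_fraction, seed=rep_seed, stratify=stratify)
            features = tuple(int(f) for f in selector(split.train, rep_seed))
            clf = clone(estimator)
            if "random_state" in clf.get_params():
                clf.set_params(random_state=rep_seed)
            clf.fit(split.train.X[:, list(features)], split.train.class_codes)
            pred = clf.predict(split.test.X[:, list(features)])
            cm = confusion(split.test.class_codes, pred, labels=range(table.n_classes))
        except Exception as exc:
            raise RuntimeError(f"repeat {i} (seed {rep_seed}) failed: {exc}") from exc
        acc = accuracy(cm)
        dr = dimensionality_reduction(len(features), oc)
        p, r, f = precision_recall_f(cm, average=average)
        records.append(
            {
                "repeat": i,
                "seed": rep_seed,
                "n_selected": len(features),
                "acc": acc,
                "dr": dr,
                "z": comprehensive_rate(acc, dr, theta),
                "precision": p,
                "recall": r,
                "f_measure": f,
            }
        )
    mean = lambda k: float(np.mean([rec[k] for rec in records]))
    return EvalReport(
        acc=mean("acc"),
        dr=mean("dr"),
        z=comprehensive_rate(mean("acc"), mean("dr"), theta),
        precision=mean("precision"),
        recall=mean("recall"),
        f_measure=mean("f_measure"),
        sc=mean("n_selected"),
        oc=oc,
        n_repeats=repeats,
        theta=theta,
        per_repeat=tuple(records),
    )
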