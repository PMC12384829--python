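"""Stratified cross-validation, best-fold selection, and metrics accounting.

The evaluation protocol mirrors the study design: 5-fold stratified CV on the
binary follow-up label, selection of the fold model with the highest held-out
Impaired recall (ties: fewest Intact-class errors, then lowest fold index),
then a final in-sample evaluation of that model on the entire dataset
(optimistically biased, and labelled as such in reports) alongside the pooled
held-out aggregate.

Impaired is the positive class throughout. Undefined ratios (zero
denominators) are reported as None, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import network as net
from .preprocessing import IMPAIRED, INTACT, TRANSITION_CLASSES

__all__ = [
    "FoldPlan",
    "FoldResult",
    "ConfusionCounts",
    "ClassMetrics",
    "ROCCurve",
    "make_stratified_folds",
    "cross_validate",
    "select_best_model",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "roc_and_auc",
    "transition_error_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for report display (0.005 -> 0.01)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray  # subject -> fold index in [0, k)
    seed: int


def make_stratified_folds(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Assign each subject to one of k folds preserving class proportions.

    Per-fold class counts differ from exact proportionality by at most one
    subject. Deterministic given the seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class ConfusionCounts:
    """Binary confusion counts with Impaired as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    valid = {INTACT, IMPAIRED}
    bad = (set(y_true) | set(y_pred)) - valid
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return ConfusionCounts(
        TP=int(np.sum((y_true == IMPAIRED) & (y_pred == IMPAIRED))),
        FP=int(np.sum((y_true == INTACT) & (y_pred == IMPAIRED))),
        TN=int(np.sum((y_true == INTACT) & (y_pred == INTACT))),
        FN=int(np.sum((y_true == IMPAIRED) & (y_pred == INTACT))),
    )


@dataclass
class FoldResult:
    fold: int
    params: net.NetworkParams
    confusion: ConfusionCounts
    test_indices: np.ndarray

    @property
    def impaired_recall(self) -> float | None:
        d = self.confusion.TP + self.confusion.FN
        return self.confusion.TP / d if d else None

    @property
    def intact_errors(self) -> int:
        return self.confusion.FP


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    plan: FoldPlan,
    train_config: net.TrainConfig | None = None,
    loss_config: net.FocalLossConfig | None = None,
    hidden_sizes: tuple[int, ...] = (7,),
) -> list[FoldResult]:
    """Train on k-1 folds, evaluate on the held-out fold, for every fold.

    Every subject is validated exactly once across the k results.
    """
    tc = train_config or net.TrainConfig()
    lc = loss_config or net.FocalLossConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    labels = net.onehot_to_labels(Y)
    results = []
    for fold in range(plan.k):
        test_mask = plan.assignments == fold
        params, _ = net.train(
            X[~test_mask],
            Y[~test_mask],
            tc,
            lc,
            init_seed=plan.seed + fold,
            hidden_sizes=hidden_sizes,
        )
        pred = net.predict(params, X[test_mask], tc.threshold)
        results.append(
            FoldResult(
                fold=fold,
                params=params,
                confusion=confusion_from_predictions(labels[test_mask], pred),
                test_indices=np.flatnonzero(test_mask),
            )
        )
    return results


def select_best_model(fold_results: list[FoldResult]) -> tuple[int, net.NetworkParams]:
    """Highest held-out Impaired recall; ties broken by fewer Intact errors,
    then lowest fold index."""
    if not fold_results:
        raise ValueError("no fold results")
    best = min(
        fold_results,
        key=lambda r: (-(r.impaired_recall if r.impaired_recall is not None else -1.0),
                       r.intact_errors,
                       r.fold),
    )
    return best.fold, best.params


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 plus micro accuracy and macro recall."""

    impaired: dict
    intact: dict
    accuracy: float
    macro_recall: float | None


def _prf(tp: int, fp: int, fn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == recall == 0:
        f1 = 0.0
    else:
        f1 = None
    return {"precision": precision, "recall": recall, "f1": f1}


def metrics_from_confusion(c: ConfusionCounts) -> ClassMetrics:
    """Precision, recall, F1 per class; micro accuracy; macro recall.

    Intact-class metrics come from swapping the positive class. Macro recall
    is the unweighted mean of the two per-class recalls.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    impaired = _prf(c.TP, c.FP, c.FN)
    intact = _prf(c.TN, c.FN, c.FP)
    accuracy = (c.TP + c.TN) / c.total
    recalls = [m["recall"] for m in (impaired, intact)]
    macro = sum(recalls) / 2 if None not in recalls else None
    return ClassMetrics(
        impaired=impaired, intact=intact, accuracy=accuracy, macro_recall=macro
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_and_auc(y_true, p_impaired) -> ROCCurve:
    """ROC over the sorted unique predicted probabilities; AUC by trapezoid.

    The trapezoidal AUC equals the rank statistic P(score_impaired >
    score_intact) with ties counted half.
    """
    y_true = np.asarray(y_true)
    p = np.asarray(p_impaired, dtype=float)
    pos = y_true == IMPAIRED
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-p, kind="mergesort")
    p_sorted = p[order]
    pos_sorted = pos[order].astype(float)
    tp_cum = np.cumsum(pos_sorted)
    fp_cum = np.cumsum(1 - pos_sorted)
    # keep the last index of each tied block of scores
    last_of_block = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tpr = np.r_[0.0, tp_cum[last_of_block] / n_pos]
    fpr = np.r_[0.0, fp_cum[last_of_block] / n_neg]
    thresholds = np.r_[np.inf, p_sorted[last_of_block]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def transition_error_table(transition_classes, y_true, y_pred) -> pd.DataFrame:
    """Per-transition-class totals and misclassification counts.

    A subject counts as misclassified when the predicted follow-up label
    differs from the true follow-up label.
    """
    transition_classes = np.asarray(transition_classes)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if not (len(transition_classes) == len(y_true) == len(y_pred)):
        raise ValueError("inputs must be aligned")
    wrong = y_true != y_pred
    rows = []
    for cls in TRANSITION_CLASSES:
        in_cls = transition_classes == cls
        rows.append(
            {
                "class": cls,
                "count": int(in_cls.sum()),
                "misclassified": int((in_cls & wrong).sum()),
            }
        )
    return pd.DataFrame(rows)
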