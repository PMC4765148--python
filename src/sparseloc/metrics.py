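"""Multi-label evaluation metrics and the leave-one-out harness.

All metrics operate on pairs of label sets (truth Y_i, prediction Y*_i),
both non-empty subsets of {1..M}.  Overall actual accuracy (OAA, exact
match) is the most stringent: a partial match contributes nothing.
Overall locative accuracy (OLA) credits every correctly predicted
location, counting a protein with k locations as k "locative proteins".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

LabelSet = set[int]
Pairs = Sequence[tuple[LabelSet, LabelSet]]


def _check(pairs: Pairs) -> None:
    if len(pairs) == 0:
        raise ValueError("need at least one (truth, prediction) pair")
    for i, (truth, pred) in enumerate(pairs):
        if not truth or not pred:
            raise ValueError(f"pair {i}: label sets must be non-empty")


def overall_actual_accuracy(pairs: Pairs) -> float:
    """Fraction of proteins whose predicted set exactly equals the truth."""
    _check(pairs)
    return sum(set(t) == set(p) for t, p in pairs) / len(pairs)


def overall_locative_accuracy(pairs: Pairs) -> float:
    """Correct locative hits over the locative total: sum|Y n Y*| / sum|Y|."""
    _check(pairs)
    hits = sum(len(set(t) & set(p)) for t, p in pairs)
    total = sum(len(t) for t, p in pairs)
    return hits / total


def multilabel_accuracy(pairs: Pairs) -> float:
    """Mean per-protein Jaccard index |Y n Y*| / |Y u Y*|."""
    _check(pairs)
    return float(np.mean([len(set(t) & set(p)) / len(set(t) | set(p)) for t, p in pairs]))


def multilabel_precision(pairs: Pairs) -> float:
    """Mean per-protein |Y n Y*| / |Y*|."""
    _check(pairs)
    return float(np.mean([len(set(t) & set(p)) / len(set(p)) for t, p in pairs]))


def multilabel_recall(pairs: Pairs) -> float:
    """Mean per-protein |Y n Y*| / |Y|."""
    _check(pairs)
    return float(np.mean([len(set(t) & set(p)) / len(set(t)) for t, p in pairs]))


def multilabel_f1(pairs: Pairs) -> float:
    """Mean per-protein 2|Y n Y*| / (|Y| + |Y*|) (harmonic mean per instance)."""
    _check(pairs)
    return float(
        np.mean([2 * len(set(t) & set(p)) / (len(set(t)) + len(set(p))) for t, p in pairs])
    )


def hamming_loss(pairs: Pairs, M: int) -> float:
    """Mean fraction of misclassified instance-label pairs: |Y xor Y*| / M."""
    _check(pairs)
    if M < 1:
        raise ValueError("M must be >= 1")
    for i, (t, p) in enumerate(pairs):
        if max(set(t) | set(p)) > M:
            raise ValueError(f"pair {i}: label exceeds M = {M}")
    return sum(len(set(t) ^ set(p)) for t, p in pairs) / (len(pairs) * M)


def _confusion(pairs: Pairs, M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tp = np.zeros(M)
    fp = np.zeros(M)
    fn = np.zeros(M)
    for t, p in pairs:
        t, p = set(t), set(p)
        for m in range(1, M + 1):
            if m in t and m in p:
                tp[m - 1] += 1
            elif m in p:
                fp[m - 1] += 1
            elif m in t:
                fn[m - 1] += 1
    return tp, fp, fn


def micro_f1(pairs: Pairs, M: int) -> float:
    """F1 of the TP/FP/FN counts pooled across all classes."""
    _check(pairs)
    tp, fp, fn = _confusion(pairs, M)
    denom = 2 * tp.sum() + fp.sum() + fn.sum()
    return float(2 * tp.sum() / denom) if denom else 0.0


def macro_f1(pairs: Pairs, M: int, include_empty_classes: bool = True) -> float:
    """Unweighted mean of per-class F1.

    A class absent from both truth and prediction everywhere contributes
    F1 = 0 by default (conservative); ``include_empty_classes=False``
    drops such classes from the average instead.
    """
    _check(pairs)
    tp, fp, fn = _confusion(pairs, M)
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    if not include_empty_classes:
        present = denom > 0
        if not present.any():
            return 0.0
        return float(f1[present].mean())
    return float(f1.mean())


def per_location_accuracy(pairs: Pairs, M: int) -> dict[int, float]:
    """Locative accuracy per location: correct hits of m / truth count of m."""
    _check(pairs)
    correct = np.zeros(M)
    total = np.zeros(M)
    for t, p in pairs:
        for m in set(t):
            total[m - 1] += 1
            if m in set(p):
                correct[m - 1] += 1
    return {
        m + 1: (correct[m] / total[m]) if total[m] else float("nan")
        for m in range(M)
    }


def locative_count(breakdown: Sequence[int]) -> int:
    """Locative proteins from a co-location histogram: sum_k k * n_k.

    ``breakdown[k-1]`` is the number of actual proteins with exactly k
    locations; a protein in k locations counts as k locative proteins.
    """
    if any(n < 0 for n in breakdown):
        raise ValueError("counts must be non-negative")
    return sum(k * n for k, n in enumerate(breakdown, start=1))


@dataclass
class EvaluationReport:
    """All nine multi-label metrics plus per-location locative accuracies."""

    oaa: float
    ola: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    micro_f1: float
    macro_f1: float
    hamming_loss: float
    per_location: dict[int, float]
    n_actual: int
    n_locative: int

    def to_json(self) -> str:
        payload = dict(self.__dict__)
        payload["per_location"] = {str(k): v for k, v in self.per_location.items()}
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        rows = [
            ("OAA", self.oaa), ("OLA", self.ola), ("Accuracy", self.accuracy),
            ("Precision", self.precision), ("Recall", self.recall),
            ("F1", self.f1), ("Micro F1", self.micro_f1),
            ("Macro F1", self.macro_f1), ("Hamming loss", self.hamming_loss),
        ]
        width = max(len(name) for name, _ in rows)
        lines = [f"{name:<{width}}  {value:.4f}" for name, value in rows]
        lines.append(f"{'N actual':<{width}}  {self.n_actual}")
        lines.append(f"{'N locative':<{width}}  {self.n_locative}")
        return "\n".join(lines)


def evaluate_pairs(pairs: Pairs, M: int) -> EvaluationReport:
    """Compute the full report for a set of (truth, prediction) pairs."""
    return EvaluationReport(
        oaa=overall_actual_accuracy(pairs),
        ola=overall_locative_accuracy(pairs),
        accuracy=multilabel_accuracy(pairs),
        precision=multilabel_precision(pairs),
        recall=multilabel_recall(pairs),
        f1=multilabel_f1(pairs),
        micro_f1=micro_f1(pairs, M),
        macro_f1=macro_f1(pairs, M),
        hamming_loss=hamming_loss(pairs, M),
        per_location=per_location_accuracy(pairs, M),
        n_actual=len(pairs),
        n_locative=sum(len(t) for t, _ in pairs),
    )


def loocv(
    items: Sequence,
    label_sets: Sequence[LabelSet],
    M: int,
    fit: Callable[[Sequence, Sequence[LabelSet]], object],
    predict: Callable[[object, object], LabelSet],
    fold_hook: Optional[Callable[[int, Sequence[int]], None]] = None,
) -> EvaluationReport:
    """Leave-one-out cross-validation of a trainer over N items.

    For each item i, ``fit`` is called on the other N-1 items and their
    labels (so feature selection and penalty tuning happen inside the
    fold), ``predict`` maps (model, held-out item) to a label set, and all
    metrics are accumulated.  ``fold_hook(i, train_indices)`` is an
    instrumentation point used to assert that the held-out protein is
    never visible during training.  Trainer failures abort with the fold
    index attached.
    """
    N = len(items)
    if N < 2:
        raise ValueError("LOOCV needs at least 2 items")
    if len(label_sets) != N:
        raise ValueError("items and label_sets length mismatch")
    pairs: list[tuple[LabelSet, LabelSet]] = []
    for i in range(N):
        train_idx = [j for j in range(N) if j != i]
        if fold_hook is not None:
            fold_hook(i, train_idx)
        try:
            model = fit([items[j] for j in train_idx], [label_sets[j] for j in train_idx])
            predicted = predict(model, items[i])
        except Exception as exc:
            exc.args = (f"LOOCV fold {i}: {exc}",)
            raise
        pairs.append((set(label_sets[i]), set(predicted)))
    return evaluate_pairs(pairs, M)
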