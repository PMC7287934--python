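"""Ranking and classification statistics for retrosynthesis predictions.

Top-N accuracy is the fraction of test products whose ground-truth reactant
set matches at least one of the first N ranked candidates. The
confidence-thresholded contingency table classifies each example's top-1
candidate: a match with confidence strictly above the threshold is a true
positive, a match at or below it a false negative, a non-match above it a
false positive and a non-match at or below it a true negative — the four
categories are exhaustive and disjoint. Precision, recall, F1, accuracy
and delta-accuracy (accuracy minus the chance agreement implied by the
table's marginals) all derive from the table:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = (TP + TN) / N
    delta     = accuracy - [(TP+FN)(TP+FP) + (TN+FN)(TN+FP)] / N^2

Zero-denominator cases return 0 with a ``degenerate`` flag rather than
failing. Fractions are computed in exact rational arithmetic where the
inputs are integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from .beam import RankedPrediction
from .smiles import reactant_set_match

__all__ = [
    "ContingencyTable",
    "top_n_accuracy",
    "contingency",
    "precision_recall_f1",
    "delta_accuracy",
    "per_class_accuracy",
    "best_f1_threshold",
    "MetricsReport",
    "compute_metrics",
]


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts of top-1 predictions under a confidence threshold."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 0.0

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _matches(prediction: RankedPrediction, truth: str, n: int, backend: str) -> bool:
    for cand in prediction.top(n):
        if cand.complete and reactant_set_match(cand.smiles, truth, backend=backend):
            return True
    return False


def top_n_accuracy(
    predictions: Sequence[RankedPrediction],
    truths: Sequence[str],
    n: int,
    backend: str = "passthrough",
) -> float:
    """Fraction of examples whose truth appears in the first n candidates."""
    if len(predictions) != len(truths):
        raise ValueError(f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not predictions:
        return 0.0
    hits = sum(_matches(p, t, n, backend) for p, t in zip(predictions, truths))
    return float(Fraction(hits, len(predictions)))


def contingency(
    predictions: Sequence[RankedPrediction],
    truths: Sequence[str],
    threshold: float,
    backend: str = "passthrough",
) -> ContingencyTable:
    """Classify each top-1 candidate into TP/FN/FP/TN under the threshold.

    "Above the threshold" is strict (>); an example with no candidates
    counts as a non-match with confidence 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if len(predictions) != len(truths):
        raise ValueError("length mismatch between predictions and truths")
    tp = fp = fn = tn = 0
    for p, truth in zip(predictions, truths):
        if p.candidates:
            score = p.candidates[0].confidence
            match = _matches(p, truth, 1, backend)
        else:
            score, match = 0.0, False
        above = score > threshold
        if match and above:
            tp += 1
        elif match:
            fn += 1
        elif above:
            fp += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold)


def precision_recall_f1(table: ContingencyTable) -> Tuple[float, float, float, bool]:
    """Returns (precision, recall, f1, degenerate).

    ``degenerate`` is True when any denominator was zero, in which case the
    affected metric is reported as 0.
    """
    degenerate = False
    if table.tp + table.fp:
        precision = Fraction(table.tp, table.tp + table.fp)
    else:
        precision, degenerate = Fraction(0), True
    if table.tp + table.fn:
        recall = Fraction(table.tp, table.tp + table.fn)
    else:
        recall, degenerate = Fraction(0), True
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = Fraction(0), True
    return float(precision), float(recall), float(f1), degenerate


def delta_accuracy(table: ContingencyTable) -> float:
    """Accuracy minus the chance agreement of the table's marginals."""
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    acc = Fraction(table.tp + table.tn, n)
    chance = Fraction(
        (table.tp + table.fn) * (table.tp + table.fp)
        + (table.tn + table.fn) * (table.tn + table.fp),
        n * n,
    )
    return float(acc - chance)


def accuracy(table: ContingencyTable) -> float:
    if table.n == 0:
        raise ValueError("empty contingency table")
    return float(Fraction(table.tp + table.tn, table.n))


def per_class_accuracy(
    predictions: Sequence[RankedPrediction],
    truths: Sequence[str],
    class_labels: Sequence[Optional[int]],
    n_values: Sequence[int] = (1, 10),
    backend: str = "passthrough",
) -> Dict[int, Dict[int, float]]:
    """Top-N accuracy restricted to each reaction class.

    Classes with no test examples are absent from the result, not zero.
    """
    if not (len(predictions) == len(truths) == len(class_labels)):
        raise ValueError("predictions, truths and class_labels must be aligned")
    by_class: Dict[int, List[int]] = {}
    for i, label in enumerate(class_labels):
        if label is None:
            raise ValueError(f"missing class label at index {i}")
        by_class.setdefault(label, []).append(i)
    out: Dict[int, Dict[int, float]] = {}
    for label, idx in sorted(by_class.items()):
        preds = [predictions[i] for i in idx]
        tr = [truths[i] for i in idx]
        out[label] = {n: top_n_accuracy(preds, tr, n, backend=backend) for n in n_values}
    return out


def best_f1_threshold(
    predictions: Sequence[RankedPrediction],
    truths: Sequence[str],
    backend: str = "passthrough",
) -> float:
    """Threshold maximizing F1 of the top-1 contingency classification.

    Candidate thresholds are the observed confidence values (strict
    'above' means each score is a potential cut); ties prefer the smallest
    threshold.
    """
    scores = sorted({p.candidates[0].confidence for p in predictions if p.candidates})
    best_t, best_f1 = 0.0, -1.0
    for t in [0.0] + scores:
        table = contingency(predictions, truths, threshold=min(t, 1.0), backend=backend)
        _, _, f1, _ = precision_recall_f1(table)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t


@dataclass
class MetricsReport:
    top_n: Dict[int, float]
    per_class: Dict[int, Dict[int, float]]
    table: ContingencyTable
    precision: float
    recall: float
    f1: float
    accuracy: float
    delta_accuracy: float
    degenerate: bool

    def as_dict(self) -> dict:
        return {
            "top_n": {str(k): v for k, v in self.top_n.items()},
            "per_class": {
                str(c): {str(n): v for n, v in d.items()} for c, d in self.per_class.items()
            },
            "contingency": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
                "threshold": self.table.threshold,
            },
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "delta_accuracy": self.delta_accuracy,
            "degenerate": self.degenerate,
        }


def compute_metrics(
    predictions: Sequence[RankedPrediction],
    truths: Sequence[str],
    class_labels: Optional[Sequence[Optional[int]]] = None,
    n_values: Sequence[int] = (1, 2, 3, 5, 10, 20),
    threshold: Optional[float] = None,
    backend: str = "passthrough",
) -> MetricsReport:
    """Full metrics bundle for one prediction run.

    When ``threshold`` is None the F1-maximizing threshold over these
    predictions is used and recorded in the table.
    """
    top_n = {n: top_n_accuracy(predictions, truths, n, backend=backend) for n in n_values}
    if threshold is None:
        threshold = best_f1_threshold(predictions, truths, backend=backend)
    table = contingency(predictions, truths, threshold, backend=backend)
    precision, recall, f1, degenerate = precision_recall_f1(table)
    per_class = (
        per_class_accuracy(predictions, truths, class_labels, backend=backend)
        if class_labels is not None
        else {}
    )
    return MetricsReport(
        top_n=top_n,
        per_class=per_class,
        table=table,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy(table),
        delta_accuracy=delta_accuracy(table),
        degenerate=degenerate,
    )
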