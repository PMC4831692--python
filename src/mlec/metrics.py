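"""Multi-label evaluation: per-label confusion counts, the four binary
indicators, macro/micro aggregates, and example-based average precision.

Per label j the binary indicators over n samples are

    accuracy  = (TP + TN) / n
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2·P·R / (P + R)

with the convention that a zero denominator yields 0. Macro aggregation
averages the indicator over labels (equal label weight); micro aggregation
applies the indicator to element-wise summed counts (equal sample weight).

Example-based average precision ranks each sample's labels by descending
score and averages, over true labels y, the fraction of ranks up to
rank(y) occupied by true labels; 1 means every true label outranks every
false one. Ranking ties are broken by ascending label index (stable sort).
Samples with no true label are excluded with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from mlec.knn import PredictionResult

logger = logging.getLogger(__name__)

INDICATORS = ("accuracy", "precision", "recall", "f_measure")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _check_shapes(true_labels, pred) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(true_labels, dtype=int)
    P = np.asarray(pred, dtype=int)
    if Y.shape != P.shape:
        raise ValueError(f"shape mismatch: truth {Y.shape} vs prediction {P.shape}")
    return Y, P


def confusion_counts(true_labels, pred, j: int) -> ConfusionCounts:
    """TP/FP/TN/FN of label j over all samples."""
    Y, P = _check_shapes(true_labels, pred)
    y, p = Y[:, j], P[:, j]
    return ConfusionCounts(
        TP=int(((y == 1) & (p == 1)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The four binary indicators with zero-denominator conventions."""
    n = c.n
    if n < 1:
        raise ValueError("empty confusion counts")
    precision = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (c.TP + c.TN) / n,
        "precision": precision,
        "recall": recall,
        "f_measure": f,
    }


def macro_micro(per_label: list[ConfusionCounts], indicator: str) -> tuple[float, float]:
    """Macro (mean over labels) and micro (summed counts) aggregates."""
    if not per_label:
        raise ValueError("need at least one label")
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    macro = float(np.mean([binary_metrics(c)[indicator] for c in per_label]))
    summed = ConfusionCounts(
        TP=sum(c.TP for c in per_label),
        FP=sum(c.FP for c in per_label),
        TN=sum(c.TN for c in per_label),
        FN=sum(c.FN for c in per_label),
    )
    return macro, binary_metrics(summed)[indicator]


def average_precision(true_labels, scores) -> float:
    """Example-based average precision of a score matrix against binary truth."""
    Y = np.asarray(true_labels, dtype=int)
    S = np.asarray(scores, dtype=float)
    if Y.shape != S.shape:
        raise ValueError(f"shape mismatch: truth {Y.shape} vs scores {S.shape}")
    keep = Y.sum(axis=1) > 0
    excluded = int((~keep).sum())
    if excluded:
        logger.info("average_precision: excluded %d sample(s) with no true label", excluded)
    if not keep.any():
        raise ValueError("no sample has a true label; average precision undefined")
    per_sample = []
    for y, s in zip(Y[keep], S[keep]):
        order = np.argsort(-s, kind="stable")  # ties → ascending label index
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(s) + 1)
        true_ranks = np.sort(ranks[y == 1])
        prefix_true = np.arange(1, len(true_ranks) + 1)
        per_sample.append(float(np.mean(prefix_true / true_ranks)))
    return float(np.mean(per_sample))


def subset_accuracy(true_labels, pred) -> float:
    """Exact-match ratio: fraction of samples whose label set is predicted exactly."""
    Y, P = _check_shapes(true_labels, pred)
    return float((Y == P).all(axis=1).mean())


@dataclass
class EvaluationReport:
    """Full measurement suite for one prediction set."""

    label_names: list[str]
    per_label_counts: list[ConfusionCounts]
    per_label_metrics: list[dict[str, float]]
    macro: dict[str, float]
    micro: dict[str, float]
    average_precision: float
    exact_match: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "labels": self.label_names,
            "per_label": [
                {"label": name, **asdict(c), **m}
                for name, c, m in zip(
                    self.label_names, self.per_label_counts, self.per_label_metrics
                )
            ],
            "macro": self.macro,
            "micro": self.micro,
            "average_precision": self.average_precision,
            "exact_match": self.exact_match,
        }


def evaluate_predictions(
    true_labels, prediction: PredictionResult, label_names: list[str] | None = None
) -> EvaluationReport:
    """Compute the complete report for a PredictionResult against binary truth."""
    Y = np.asarray(true_labels, dtype=int)
    P = prediction.bipartition
    if Y.shape != P.shape:
        raise ValueError(f"shape mismatch: truth {Y.shape} vs prediction {P.shape}")
    m = Y.shape[1]
    if label_names is None:
        label_names = [f"EC{j + 1}" for j in range(m)]
    counts = [confusion_counts(Y, P, j) for j in range(m)]
    per_metrics = [binary_metrics(c) for c in counts]
    macro = {}
    micro = {}
    for ind in INDICATORS:
        macro[ind], micro[ind] = macro_micro(counts, ind)
    return EvaluationReport(
        label_names=list(label_names),
        per_label_counts=counts,
        per_label_metrics=per_metrics,
        macro=macro,
        micro=micro,
        average_precision=average_precision(Y, prediction.scores),
        exact_match=subset_accuracy(Y, P),
        n_samples=Y.shape[0],
    )
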