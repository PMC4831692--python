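"""Score/bipartition fusion rules for classifier ensembles.

Three rules combine, per sample, the outputs of m member classifiers over
the label set: the mean of scores, a strict-majority vote on bipartitions,
and the top-K rule that averages only the K largest member scores per label.
The TOP3 preset — top-K with K = 3 over five members — is the configuration
that fuses all five multi-label classifiers this toolkit and its comparison
set cover.
"""

from __future__ import annotations

import numpy as np

from mlec.knn import PredictionResult


def _as_score_matrix(scores) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 1:
        raise ValueError("expected a non-empty (classifiers × labels) matrix")
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return scores


def mean_score(scores) -> np.ndarray:
    """Per-label mean of member-classifier scores."""
    return _as_score_matrix(scores).mean(axis=0)


def majority_bipartition(bips) -> np.ndarray:
    """Strict majority vote: label assigned iff more than half of the
    classifiers assign it."""
    bips = np.asarray(bips)
    if bips.ndim != 2 or bips.shape[0] < 1:
        raise ValueError("expected a non-empty (classifiers × labels) matrix")
    if not np.isin(bips, (0, 1)).all():
        raise ValueError("bipartitions must be binary")
    m = bips.shape[0]
    return (bips.sum(axis=0) > m / 2).astype(int)


def topk_score(scores, K: int) -> np.ndarray:
    """Per-label mean of the K largest member scores."""
    scores = _as_score_matrix(scores)
    m = scores.shape[0]
    if not 1 <= K <= m:
        raise ValueError(f"K must be in [1, {m}], got {K}")
    top = np.sort(scores, axis=0)[::-1][:K]
    return top.mean(axis=0)


def threshold_scores(combined, t: float = 0.5) -> np.ndarray:
    """Binarize a combined score vector: assign iff score > t.

    If nothing clears the threshold, the single top-scoring label (lowest
    index on ties) is assigned — an enzyme always has at least one class.
    """
    if not 0 <= t <= 1:
        raise ValueError("threshold must be in [0, 1]")
    combined = np.asarray(combined, dtype=float)
    out = (combined > t).astype(int)
    if out.sum() == 0 and combined.size:
        out[combined.argmax()] = 1
    return out


def combine_predictions(
    results: list[PredictionResult],
    rule: str = "mean",
    K: int = 3,
    threshold: float = 0.5,
) -> PredictionResult:
    """Fuse member PredictionResults sample-by-sample.

    ``rule`` is one of ``mean``, ``majority``, ``topk``. For score rules the
    combined scores are thresholded per sample; for the majority rule the
    reported score is the vote fraction.
    """
    if not results:
        raise ValueError("need at least one member classifier result")
    scores = np.stack([r.scores for r in results])  # c × n × m
    bips = np.stack([r.bipartition for r in results])
    n = scores.shape[1]
    out_scores = np.empty(scores.shape[1:])
    out_bip = np.empty(scores.shape[1:], dtype=int)
    for i in range(n):
        if rule == "mean":
            combined = mean_score(scores[:, i, :])
            out_scores[i], out_bip[i] = combined, threshold_scores(combined, threshold)
        elif rule == "topk":
            combined = topk_score(scores[:, i, :], K)
            out_scores[i], out_bip[i] = combined, threshold_scores(combined, threshold)
        elif rule == "majority":
            out_scores[i] = bips[:, i, :].mean(axis=0)
            out_bip[i] = majority_bipartition(bips[:, i, :])
        else:
            raise ValueError(f"unknown ensemble rule {rule!r}")
    return PredictionResult(scores=out_scores, bipartition=out_bip)
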