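"""KNN-kernel classifiers: single-label IB1 and multi-label MLkNN / BRkNN / IBLR-ML.

All classifiers share one neighbor search: brute-force Euclidean distances
with ties at equal distance broken by ascending training index, so results
are deterministic. Each multi-label classifier emits per-label scores in
[0, 1] and a bipartition; the decision rule is strictly-greater-than 0.5
except where a documented fallback applies.

MLkNN scores are Bayesian posteriors over the count of neighbors carrying a
label, with Laplace-smoothed priors and conditionals. BRkNN scores are raw
neighbor label fractions, with an empty-prediction fallback that assigns the
single top-scoring label (every enzyme has at least one class). IBLR-ML
stacks a per-label logistic regression on top of the neighbor label-fraction
meta-features, computed leave-one-out on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression

from mlec.dataset import MultiLabelDataset


@dataclass
class PredictionResult:
    """Per-label scores in [0,1] and the induced binary bipartition."""

    scores: np.ndarray
    bipartition: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.bipartition = np.asarray(self.bipartition, dtype=int)
        if self.scores.shape != self.bipartition.shape:
            raise ValueError("scores and bipartition shapes differ")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class NeighborModel:
    """Stored training set plus neighbor-search configuration."""

    train_features: np.ndarray
    train_labels: np.ndarray
    k: int
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.train_features = np.asarray(self.train_features, dtype=float)
        self.train_labels = np.asarray(self.train_labels, dtype=int)
        n = self.train_features.shape[0]
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds {n} training samples")
        if self.train_labels.shape[0] != n:
            raise ValueError("feature/label row mismatch")

    @property
    def n(self) -> int:
        return self.train_features.shape[0]


def _check_query_dim(model: NeighborModel, queries: np.ndarray) -> np.ndarray:
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.train_features.shape[1]:
        raise ValueError(
            f"query dimension {queries.shape[1]} != training dimension "
            f"{model.train_features.shape[1]}"
        )
    return queries


def kneighbors(
    model: NeighborModel, queries: np.ndarray, exclude_self: bool = False
) -> np.ndarray:
    """Indices of the k nearest training points per query row.

    Stable argsort breaks distance ties by ascending training index. With
    ``exclude_self=True`` (queries are the training set itself) the diagonal
    is removed before ranking.
    """
    queries = _check_query_dim(model, queries)
    dist = cdist(queries, model.train_features, metric=model.metric)
    if exclude_self:
        if dist.shape[0] != dist.shape[1]:
            raise ValueError("exclude_self requires queries == training set")
        np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, : model.k]


def knn_predict_single(model: NeighborModel, queries: np.ndarray) -> np.ndarray:
    """Single-label majority vote among the k nearest neighbors (IB1 at k=1).

    Training labels must be single-label (one-hot rows). Vote ties are
    broken by the lowest class index.
    """
    if not (model.train_labels.sum(axis=1) == 1).all():
        raise ValueError("knn_predict_single requires single-label training data")
    classes = model.train_labels.argmax(axis=1)
    idx = kneighbors(model, queries)
    m = model.train_labels.shape[1]
    votes = np.apply_along_axis(
        lambda row: np.bincount(classes[row], minlength=m), 1, idx
    )
    return votes.argmax(axis=1)


# ---------------------------------------------------------------------------
# MLkNN


@dataclass
class MLkNNModel:
    """Laplace-smoothed priors and neighbor-count conditionals per label."""

    neighbors: NeighborModel
    smoothing: float
    prior: np.ndarray  # P(label present), m
    cond_present: np.ndarray  # P(c neighbors | present), m × (k+1)
    cond_absent: np.ndarray  # P(c neighbors | absent), m × (k+1)

    def __post_init__(self) -> None:
        for arr in (self.prior, self.cond_present, self.cond_absent):
            if ((arr <= 0) | (arr >= 1)).any():
                raise ValueError("smoothed probabilities must lie strictly in (0,1)")


def _neighbor_label_counts(
    model: NeighborModel, queries: np.ndarray, exclude_self: bool = False
) -> np.ndarray:
    idx = kneighbors(model, queries, exclude_self=exclude_self)
    return model.train_labels[idx].sum(axis=1)


def mlknn_fit(
    train: MultiLabelDataset, k: int = 10, s: float = 1.0, metric: str = "euclidean"
) -> MLkNNModel:
    """Fit MLkNN: smoothed label priors plus neighbor-count conditionals.

    Priors: P(H_j) = (s + n_j) / (2s + n). Conditionals: for each label j
    and count c in 0..k, the smoothed frequency of training samples with
    exactly c of their k nearest neighbors (self excluded) carrying j,
    among samples that do / do not carry j themselves.
    """
    n, m = train.Y.shape
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nm = NeighborModel(train.X, train.Y, k=k, metric=metric)
    prior = (s + train.Y.sum(axis=0)) / (2 * s + n)
    counts = _neighbor_label_counts(nm, train.X, exclude_self=True)  # n × m
    cond_present = np.empty((m, k + 1))
    cond_absent = np.empty((m, k + 1))
    for j in range(m):
        present = train.Y[:, j] == 1
        kj = np.bincount(counts[present, j], minlength=k + 1)
        kj_bar = np.bincount(counts[~present, j], minlength=k + 1)
        cond_present[j] = (s + kj) / (s * (k + 1) + kj.sum())
        cond_absent[j] = (s + kj_bar) / (s * (k + 1) + kj_bar.sum())
    return MLkNNModel(
        neighbors=nm,
        smoothing=s,
        prior=prior,
        cond_present=cond_present,
        cond_absent=cond_absent,
    )


def mlknn_predict(model: MLkNNModel, queries: np.ndarray) -> PredictionResult:
    """Posterior P(label | neighbor count) per query; assign when > 0.5."""
    counts = _neighbor_label_counts(model.neighbors, queries)
    m = model.prior.shape[0]
    cols = np.arange(m)
    num = model.prior[cols] * model.cond_present[cols, counts]
    den = num + (1 - model.prior[cols]) * model.cond_absent[cols, counts]
    scores = num / den
    return PredictionResult(scores=scores, bipartition=(scores > 0.5).astype(int))


# ---------------------------------------------------------------------------
# BRkNN


def brknn_predict(model: NeighborModel, queries: np.ndarray) -> PredictionResult:
    """Binary-relevance kNN: score = neighbor label fraction.

    Labels with fraction strictly above 0.5 are assigned; if none is, the
    single top-scoring label (lowest index on ties) is assigned instead.
    """
    counts = _neighbor_label_counts(model, queries)
    scores = counts / model.k
    bip = (scores > 0.5).astype(int)
    empty = bip.sum(axis=1) == 0
    if empty.any():
        top = scores[empty].argmax(axis=1)
        bip[np.flatnonzero(empty), top] = 1
    return PredictionResult(scores=scores, bipartition=bip)


# ---------------------------------------------------------------------------
# IBLR-ML


@dataclass
class IBLRModel:
    neighbors: NeighborModel
    learners: list = field(default_factory=list)  # LogisticRegression or float fallback


def _label_fraction_meta(model: NeighborModel, queries, exclude_self=False):
    return _neighbor_label_counts(model, queries, exclude_self) / model.k


def iblr_fit(train: MultiLabelDataset, k: int = 10, metric: str = "euclidean") -> IBLRModel:
    """Fit IBLR-ML: per-label logistic regression over the m neighbor
    label-fraction meta-features (leave-one-out on the training set).

    A label constant across training data gets no logistic model; its score
    falls back to the empirical prior clipped to (0.01, 0.99).
    """
    n, m = train.Y.shape
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nm = NeighborModel(train.X, train.Y, k=k, metric=metric)
    meta = _label_fraction_meta(nm, train.X, exclude_self=True)
    learners = []
    for j in range(m):
        y = train.Y[:, j]
        if y.min() == y.max():
            learners.append(float(np.clip(y.mean(), 0.01, 0.99)))
        else:
            clf = LogisticRegression(max_iter=1000)
            clf.fit(meta, y)
            learners.append(clf)
    return IBLRModel(neighbors=nm, learners=learners)


def iblr_predict(model: IBLRModel, queries: np.ndarray) -> PredictionResult:
    meta = _label_fraction_meta(model.neighbors, queries)
    nq = meta.shape[0]
    scores = np.empty((nq, len(model.learners)))
    for j, learner in enumerate(model.learners):
        if isinstance(learner, float):
            scores[:, j] = learner
        else:
            scores[:, j] = learner.predict_proba(meta)[:, 1]
    return PredictionResult(scores=scores, bipartition=(scores > 0.5).astype(int))


# ---------------------------------------------------------------------------
# Uniform fit/predict wrappers for the pipeline


class _BaseClassifier:
    name = "base"

    def fit(self, train: MultiLabelDataset) -> "_BaseClassifier":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> PredictionResult:
        raise NotImplementedError


class MLkNN(_BaseClassifier):
    name = "mlknn"

    def __init__(self, k: int = 10, s: float = 1.0):
        self.k, self.s = k, s
        self._model: MLkNNModel | None = None

    def fit(self, train):
        self._model = mlknn_fit(train, k=self.k, s=self.s)
        return self

    def predict(self, X):
        return mlknn_predict(self._model, X)


class BRkNN(_BaseClassifier):
    name = "brknn"

    def __init__(self, k: int = 10):
        self.k = k
        self._model: NeighborModel | None = None

    def fit(self, train):
        self._model = NeighborModel(train.X, train.Y, k=self.k)
        return self

    def predict(self, X):
        return brknn_predict(self._model, X)


class IBLRClassifier(_BaseClassifier):
    name = "iblr"

    def __init__(self, k: int = 10):
        self.k = k
        self._model: IBLRModel | None = None

    def fit(self, train):
        self._model = iblr_fit(train, k=self.k)
        return self

    def predict(self, X):
        return iblr_predict(self._model, X)


class IB1Classifier(_BaseClassifier):
    """1-nearest-neighbor single-label classifier, exposed as one-hot output.

    Multi-label training rows are collapsed to their lowest active label;
    intended for single-label data.
    """

    name = "ib1"

    def __init__(self, k: int = 1):
        self.k = k
        self._model: NeighborModel | None = None

    def fit(self, train):
        Y = train.Y
        if not (Y.sum(axis=1) == 1).all():
            # collapse to lowest active label to keep IB1 well-defined
            onehot = np.zeros_like(Y)
            onehot[np.arange(len(Y)), Y.argmax(axis=1)] = 1
            Y = onehot
        self._model = NeighborModel(train.X, Y, k=self.k)
        return self

    def predict(self, X):
        cls = knn_predict_single(self._model, X)
        m = self._model.train_labels.shape[1]
        out = np.zeros((len(cls), m), dtype=int)
        out[np.arange(len(cls)), cls] = 1
        return PredictionResult(scores=out.astype(float), bipartition=out)
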