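"""In-memory container for a featurized multi-label dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultiLabelDataset:
    """n feature vectors paired with an n×m binary label matrix.

    Rows are aligned: ``ids[i]`` owns feature row ``X[i]`` and label row
    ``Y[i]``. Labels default to the six EC top-level classes.
    """

    ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=int)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D arrays")
        n = len(self.ids)
        if self.X.shape[0] != n or self.Y.shape[0] != n:
            raise ValueError(
                f"row mismatch: {n} ids, {self.X.shape[0]} feature rows, "
                f"{self.Y.shape[0]} label rows"
            )
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("label matrix must be binary")
        if not self.label_names:
            self.label_names = [f"EC{j + 1}" for j in range(self.Y.shape[1])]
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def cardinality(self) -> np.ndarray:
        """Number of active labels per sample."""
        return self.Y.sum(axis=1)

    def subset(self, idx: np.ndarray) -> "MultiLabelDataset":
        idx = np.asarray(idx)
        return MultiLabelDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            Y=self.Y[idx],
            feature_names=list(self.feature_names),
            label_names=list(self.label_names),
        )
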