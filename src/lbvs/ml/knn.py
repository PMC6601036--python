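"""k-nearest-neighbor classifier (Euclidean metric, majority vote)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset
from .forest import PredictionResult


@dataclass
class KNNModel:
    k: int
    X: np.ndarray
    y: np.ndarray
    ids: list[str]


def train_knn(train: LabeledDataset, k: int = 6) -> KNNModel:
    """Store the (standardized) training set; k must not exceed its size."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train.n:
        raise ValueError("k exceeds training size")
    return KNNModel(k, train.X.copy(), train.y.copy(), list(train.ids))


def knn_predict(model: KNNModel, X: np.ndarray, ids=None) -> list[PredictionResult]:
    """Majority vote of the k nearest training points.

    Distance ties resolve to the lower training index (stable argsort);
    a split vote goes to the nearest neighbor's class.  Score = fraction
    of actives among the k neighbors.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
    out = []
    for row, mol_id in zip(X, ids):
        d = np.sqrt(((model.X - row) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[: model.k]
        votes = model.y[nn]
        n_pos = int((votes == 1).sum())
        if 2 * n_pos != model.k:
            label = 1 if 2 * n_pos > model.k else -1
        else:
            label = int(votes[0])  # tie: class of the nearest neighbor
        out.append(PredictionResult(mol_id, label, n_pos / model.k))
    return out
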