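"""Labeled datasets, stratified splitting and feature standardization."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

LABELS = (1, -1)


@dataclass
class LabeledDataset:
    """Feature matrix plus ±1 activity labels, columns in registry order."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    scaler: "Scaler | None" = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.ids) != self.X.shape[0] != len(self.y):
            raise ValueError("inconsistent dataset shapes")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature names")
        if not set(np.unique(self.y)) <= set(LABELS):
            raise ValueError("labels must lie in {+1, -1}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            [self.ids[i] for i in idx], self.X[idx], self.y[idx],
            list(self.feature_names), self.scaler,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, labels: Sequence[int]) -> "LabeledDataset":
        return cls(list(df.index.astype(str)), df.to_numpy(float),
                   np.asarray(labels, int), list(df.columns))


@dataclass(frozen=True)
class Scaler:
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # column indices retained (zero-variance columns dropped)


def impute_median(train: LabeledDataset, *others: LabeledDataset):
    """Replace missing (NaN) values by training-set column medians.

    Columns that are entirely missing in the training set are filled with 0.
    """
    med = np.nanmedian(train.X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)

    def fill(d: LabeledDataset) -> LabeledDataset:
        X = d.X.copy()
        nan = ~np.isfinite(X)
        X[nan] = np.broadcast_to(med, X.shape)[nan]
        return replace(d, X=X)

    out = [fill(train)] + [fill(d) for d in others]
    return out[0] if not others else tuple(out)


def split_dataset(
    d: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified-by-class random split, reproducible by seed.

    The training share of each class is rounded to the nearest integer,
    so 1457 compounds at 2/3 give the 971/486 train/test sizes.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in LABELS:
        members = np.flatnonzero(d.y == label)
        if members.size == 0:
            continue
        if members.size < 2:
            raise ValueError(f"class {label:+d} has fewer than 2 members")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return d.subset(np.sort(train_idx)), d.subset(np.sort(test_idx))


def standardize_features(
    train: LabeledDataset, test: LabeledDataset | None = None
):
    """Z-score both sets with training statistics; drop constant columns."""
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=0)
    # treat numerically-constant columns as constant
    kept = np.flatnonzero(sd > 1e-10 * np.maximum(1.0, np.abs(mean)))
    scaler = Scaler(mean[kept], sd[kept], kept)

    def apply(d: LabeledDataset) -> LabeledDataset:
        X = (d.X[:, kept] - scaler.mean) / scaler.sd
        return LabeledDataset(
            list(d.ids), X, d.y.copy(),
            [d.feature_names[i] for i in kept], scaler,
        )

    if test is None:
        return apply(train), scaler
    return apply(train), apply(test), scaler
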