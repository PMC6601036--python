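"""Random forest with out-of-bag (OOB) bookkeeping, tuning and importance.

The forest grows ``n_tree`` unpruned CART trees on bootstrap samples of the
training set, each node splitting on the best of ``m_try`` randomly chosen
descriptors, and predicts by consensus voting.  The fraction of trees
voting "active" is the *relative probability score* used for screening.
Samples left out of a tree's bootstrap bag ("out of bag") provide the
internal OOB error estimate that drives hyperparameter tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cart import CARTTree, grow_tree
from .data import LabeledDataset


@dataclass
class PredictionResult:
    id: str
    label: int
    score: float  # fraction of trees voting +1; in [0, 1]


@dataclass
class RandomForestModel:
    m_try: int
    n_tree: int
    trees: list[CARTTree]
    bags: list[np.ndarray]            # bootstrap sample indices per tree
    oob_votes: np.ndarray             # (n_train, 2): votes for -1, +1 from OOB trees
    feature_names: list[str]
    seed: int

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Relative probability score per row: fraction of +1 votes."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pos = np.zeros(X.shape[0])
        for t in self.trees:
            pos += t.predict(X) == 1
        return pos / len(self.trees)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        """Majority vote; an exact tie predicts inactive (-1)."""
        return np.where(self.scores(X) > 0.5, 1, -1)

    def predict(self, X: np.ndarray, ids: Sequence[str] | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = self.scores(X)
        ids = list(ids) if ids is not None else [str(i) for i in range(len(s))]
        return [
            PredictionResult(i, 1 if sc > 0.5 else -1, float(sc))
            for i, sc in zip(ids, s)
        ]


def train_random_forest(
    train: LabeledDataset, m_try: int, n_tree: int, seed: int
) -> RandomForestModel:
    """Grow the forest and populate per-sample OOB vote tallies."""
    if not 1 <= m_try <= train.p:
        raise ValueError("m_try must lie in [1, feature count]")
    if np.unique(train.y).size < 2:
        warnings.warn("single-class training set: forest is a constant model")
    rng = np.random.default_rng(seed)
    n = train.n
    trees: list[CARTTree] = []
    bags: list[np.ndarray] = []
    oob_votes = np.zeros((n, 2), dtype=np.int64)
    for _ in range(n_tree):
        bag = rng.integers(0, n, size=n)
        tree = grow_tree(train.X[bag], train.y[bag], m_try=m_try, rng=rng)
        oob = np.setdiff1d(np.arange(n), bag, assume_unique=False)
        if oob.size:
            pred = tree.predict(train.X[oob])
            oob_votes[oob[pred == -1], 0] += 1
            oob_votes[oob[pred == 1], 1] += 1
        trees.append(tree)
        bags.append(bag)
    return RandomForestModel(
        m_try, n_tree, trees, bags, oob_votes, list(train.feature_names), seed
    )


def rf_oob_error(model: RandomForestModel, train: LabeledDataset) -> float:
    """OOB prediction error rate over the training samples.

    Each sample is voted on only by trees whose bag excluded it; samples
    never out of bag are dropped from the denominator.
    """
    votes = model.oob_votes
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        raise ValueError("no OOB coverage; increase n_tree")
    pred = np.where(votes[covered, 1] > votes[covered, 0], 1, -1)
    return float(np.mean(pred != train.y[covered]))


def test_per(model: RandomForestModel, test: LabeledDataset) -> float:
    """Plain misclassification rate of the full-forest vote on a test set."""
    if test.n == 0:
        raise ValueError("empty test set")
    return float(np.mean(model.predict_labels(test.X) != test.y))


def select_best(scan: pd.DataFrame) -> pd.Series:
    """Pick the winning grid row: lowest test PER, then lowest training
    (OOB) PER, then smaller n_tree, then smaller m_try."""
    ordered = scan.sort_values(
        ["test_per", "train_per", "n_tree", "m_try"], kind="stable"
    )
    return ordered.iloc[0]


def tune_rf(
    train: LabeledDataset,
    test: LabeledDataset,
    m_try_grid: Sequence[int],
    n_tree_grid: Sequence[int],
    seed: int,
    reference_n_tree: int = 500,
) -> tuple[int, int, pd.DataFrame]:
    """Two-stage grid scan of the forest hyperparameters.

    Stage 1 scans ``m_try`` at the fixed reference forest size; stage 2
    fixes the winning ``m_try`` and scans ``n_tree``.  Both stages minimize
    the test-set prediction error rate, breaking ties by lower training
    (OOB) error, then smaller forest.  The full scan table is returned for
    histogram-style inspection.
    """
    if not len(m_try_grid) or not len(n_tree_grid):
        raise ValueError("empty tuning grid")
    rows = []
    for m in m_try_grid:
        model = train_random_forest(train, m, reference_n_tree, seed)
        rows.append({
            "stage": 1, "m_try": m, "n_tree": reference_n_tree,
            "test_per": test_per(model, test),
            "train_per": rf_oob_error(model, train),
        })
    stage1 = pd.DataFrame(rows)
    best_m = int(select_best(stage1)["m_try"])
    rows2 = []
    for nt in n_tree_grid:
        model = train_random_forest(train, best_m, nt, seed)
        rows2.append({
            "stage": 2, "m_try": best_m, "n_tree": nt,
            "test_per": test_per(model, test),
            "train_per": rf_oob_error(model, train),
        })
    stage2 = pd.DataFrame(rows2)
    best = select_best(stage2)
    scan = pd.concat([stage1, stage2], ignore_index=True)
    return best_m, int(best["n_tree"]), scan


def rf_feature_importance(
    model: RandomForestModel, train: LabeledDataset, seed: int
) -> list[tuple[str, float]]:
    """Breiman permutation importance, descending.

    Per tree: accuracy on its OOB samples minus accuracy after permuting
    one feature's values within those samples; averaged over trees.
    """
    rng = np.random.default_rng(seed)
    n, p = train.X.shape
    drops = np.zeros(p)
    counts = np.zeros(p)
    all_idx = np.arange(n)
    for tree, bag in zip(model.trees, model.bags):
        oob = np.setdiff1d(all_idx, bag)
        if oob.size < 2:
            continue
        Xo = train.X[oob]
        yo = train.y[oob]
        base = np.mean(tree.predict(Xo) == yo)
        used = {nd.feature for nd in tree.nodes if nd.feature >= 0}
        for f in range(p):
            if f not in used:
                continue  # unused feature: permutation cannot change output
            Xp = Xo.copy()
            Xp[:, f] = Xp[rng.permutation(oob.size), f]
            drops[f] += base - np.mean(tree.predict(Xp) == yo)
            counts[f] += 1
        for f in range(p):
            if f not in used:
                counts[f] += 1  # contributes a zero drop
    imp = np.divide(drops, np.maximum(counts, 1))
    order = np.argsort(-imp, kind="stable")
    return [(model.feature_names[f], float(imp[f])) for f in order]


def select_top(ranking: list[tuple[str, float]], n: int) -> list[str]:
    """Names of the n most important descriptors."""
    return [name for name, _ in ranking[:n]]
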