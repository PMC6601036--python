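"""C4.5-style decision tree: gain-ratio splits, pessimistic error pruning.

Continuous features only (the descriptor table is numeric): each non-leaf
node tests ``x[f] <= threshold``.  The split maximizes the gain ratio
(information gain over split information) among candidate thresholds with
positive gain.  Pruning replaces a subtree by a leaf when the leaf's
pessimistic error estimate — the Clopper–Pearson upper confidence bound on
the training error at the given confidence — does not exceed the subtree's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import LabeledDataset
from .forest import PredictionResult


@dataclass
class C45Node:
    feature: int = -1
    threshold: float = 0.0
    left: "C45Node | None" = None
    right: "C45Node | None" = None
    label: int = 0
    n_pos: int = 0
    n_total: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


@dataclass
class C45Model:
    root: C45Node
    pruning_confidence: float
    feature_names: list[str]


def _entropy(n_pos: int, n: int) -> float:
    if n == 0 or n_pos in (0, n):
        return 0.0
    p = n_pos / n
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def gain_ratio(y01: np.ndarray, go_left: np.ndarray) -> float:
    """Information gain over split information for a binary partition.

    Zero when either side is empty or the split leaves the class
    distribution unchanged on both sides.
    """
    n = y01.size
    nl = int(go_left.sum())
    nr = n - nl
    if nl == 0 or nr == 0:
        return 0.0
    pos = int(y01.sum())
    pos_l = int(y01[go_left].sum())
    gain = _entropy(pos, n) - (
        nl * _entropy(pos_l, nl) + nr * _entropy(pos - pos_l, nr)
    ) / n
    if gain <= 1e-12:
        return 0.0
    split_info = _entropy(nl, n)
    return gain / split_info if split_info > 0 else 0.0


def _best_split(X: np.ndarray, y01: np.ndarray):
    best = (None, 0.0, 0.0)  # feature, threshold, gain ratio
    for f in range(X.shape[1]):
        xs = np.sort(np.unique(X[:, f]))
        if xs.size < 2:
            continue
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (lo + hi)
            gr = gain_ratio(y01, X[:, f] <= thr)
            if gr > best[2] + 1e-12:
                best = (f, thr, gr)
    return best


def pessimistic_error(n_errors: int, n: int, confidence: float) -> float:
    """Upper confidence bound on the node error rate (C4.5's U_CF)."""
    if n == 0:
        return 0.0
    if n_errors >= n:
        return 1.0
    return float(stats.beta.ppf(1.0 - confidence, n_errors + 1, n - n_errors))


def _grow(X, y01, depth_cap: int) -> C45Node:
    n = y01.size
    pos = int(y01.sum())
    label = 1 if 2 * pos > n else -1
    node = C45Node(label=label, n_pos=pos, n_total=n)
    if pos in (0, n) or depth_cap == 0:
        return node
    f, thr, gr = _best_split(X, y01)
    if f is None or gr <= 0.0:
        return node
    go_left = X[:, f] <= thr
    node.feature, node.threshold = int(f), float(thr)
    node.left = _grow(X[go_left], y01[go_left], depth_cap - 1)
    node.right = _grow(X[~go_left], y01[~go_left], depth_cap - 1)
    return node


def _prune(node: C45Node, confidence: float) -> float:
    """Return the subtree's estimated error count; collapse where a leaf
    is pessimistically no worse."""
    n = node.n_total
    errors_as_leaf = min(node.n_pos, n - node.n_pos)
    leaf_estimate = n * pessimistic_error(errors_as_leaf, n, confidence)
    if node.is_leaf:
        return leaf_estimate
    subtree_estimate = _prune(node.left, confidence) + _prune(node.right, confidence)
    if leaf_estimate <= subtree_estimate:
        node.feature, node.left, node.right = -1, None, None
        return leaf_estimate
    return subtree_estimate


def train_c45(
    train: LabeledDataset, pruning_confidence: float = 0.25,
    max_depth: int = 64,
) -> C45Model:
    if np.unique(train.y).size < 2:
        raise ValueError("C4.5 training needs both classes present")
    y01 = (train.y == 1).astype(np.int64)
    root = _grow(train.X, y01, max_depth)
    _prune(root, pruning_confidence)
    return C45Model(root, pruning_confidence, list(train.feature_names))


def c45_predict(model: C45Model, X: np.ndarray, ids=None) -> list[PredictionResult]:
    """Root-to-leaf walk; score = active fraction of the leaf's support."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
    out = []
    for row, mol_id in zip(X, ids):
        node = model.root
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        score = node.n_pos / node.n_total if node.n_total else 0.5
        out.append(PredictionResult(mol_id, node.label, float(score)))
    return out
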