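"""CART trees with Gini impurity and random feature subsampling.

The building block of the random forest: unpruned binary trees grown to
purity (minimum node size 1), each node splitting on the best of ``m_try``
uniformly sampled candidate features.  Split search per feature is the
standard sort-and-scan over midpoints, vectorized with cumulative class
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class _Node:
    feature: int = -1          # -1 marks a leaf
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    label: int = 0
    n_pos: int = 0
    n_total: int = 0


@dataclass
class CARTTree:
    nodes: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0], dtype=int)
        for r in range(X.shape[0]):
            i = 0
            node = self.nodes[0]
            while node.feature >= 0:
                i = node.left if X[r, node.feature] <= node.threshold else node.right
                node = self.nodes[i]
            out[r] = node.label
        return out


def _best_split(X, y01, features, rng):
    """Best (feature, threshold, gini gain) over candidate features."""
    n = y01.size
    parent_pos = int(y01.sum())
    best = (None, 0.0, 0.0)
    for f in features:
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y01[order]
        # candidate cut after position i where value changes
        cum_pos = np.cumsum(ys)
        idx = np.flatnonzero(xs[:-1] < xs[1:])
        if idx.size == 0:
            continue
        n_left = idx + 1
        n_right = n - n_left
        pos_left = cum_pos[idx]
        pos_right = parent_pos - pos_left
        gini_left = 1.0 - (pos_left / n_left) ** 2 - (1 - pos_left / n_left) ** 2
        gini_right = (
            1.0 - (pos_right / n_right) ** 2 - (1 - pos_right / n_right) ** 2
        )
        parent_gini = (
            1.0 - (parent_pos / n) ** 2 - (1 - parent_pos / n) ** 2
        )
        gain = parent_gini - (n_left * gini_left + n_right * gini_right) / n
        k = int(np.argmax(gain))
        if gain[k] > best[2] + 1e-15:
            thr = 0.5 * (xs[idx[k]] + xs[idx[k] + 1])
            best = (f, thr, float(gain[k]))
    return best


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    m_try: int | None = None,
    rng: np.random.Generator | None = None,
) -> CARTTree:
    """Grow an unpruned CART tree; ``m_try`` features sampled per node."""
    rng = rng or np.random.default_rng(0)
    p = X.shape[1]
    m_try = p if m_try is None else min(m_try, p)
    y01 = (y == 1).astype(np.int64)
    tree = CARTTree()

    def leaf(idx) -> int:
        pos = int(y01[idx].sum())
        n = idx.size
        label = 1 if pos * 2 > n else -1  # tie -> inactive (conservative)
        tree.nodes.append(_Node(label=label, n_pos=pos, n_total=n))
        return len(tree.nodes) - 1

    def build(idx) -> int:
        pos = int(y01[idx].sum())
        if pos == 0 or pos == idx.size:
            return leaf(idx)
        features = rng.choice(p, size=m_try, replace=False)
        f, thr, gain = _best_split(X[idx], y01[idx], features, rng)
        if f is None or gain <= 0.0:
            return leaf(idx)
        me = len(tree.nodes)
        tree.nodes.append(_Node(feature=int(f), threshold=float(thr),
                                n_pos=pos, n_total=idx.size))
        go_left = X[idx, f] <= thr
        tree.nodes[me].left = build(idx[go_left])
        tree.nodes[me].right = build(idx[~go_left])
        return me

    build(np.arange(X.shape[0]))
    return tree
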