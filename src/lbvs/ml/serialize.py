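"""JSON model container (format-versioned) for all four classifiers."""

from __future__ import annotations

import json

import numpy as np

from .c45 import C45Model, C45Node
from .cart import CARTTree, _Node
from .forest import RandomForestModel
from .knn import KNNModel
from .svm import SVMModel

FORMAT_VERSION = "1"


def _tree_to_obj(t: CARTTree) -> list:
    return [
        [n.feature, n.threshold, n.left, n.right, n.label, n.n_pos, n.n_total]
        for n in t.nodes
    ]


def _tree_from_obj(obj: list) -> CARTTree:
    return CARTTree([_Node(*row) for row in obj])


def _c45_to_obj(node: C45Node):
    d = {"label": node.label, "n_pos": node.n_pos, "n_total": node.n_total}
    if not node.is_leaf:
        d.update(
            feature=node.feature, threshold=node.threshold,
            left=_c45_to_obj(node.left), right=_c45_to_obj(node.right),
        )
    return d


def _c45_from_obj(d) -> C45Node:
    node = C45Node(label=d["label"], n_pos=d["n_pos"], n_total=d["n_total"])
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = d["threshold"]
        node.left = _c45_from_obj(d["left"])
        node.right = _c45_from_obj(d["right"])
    return node


def save_model(model, path) -> None:
    if isinstance(model, RandomForestModel):
        payload = {
            "kind": "random_forest",
            "m_try": model.m_try, "n_tree": model.n_tree, "seed": model.seed,
            "feature_names": model.feature_names,
            "trees": [_tree_to_obj(t) for t in model.trees],
            "bags": [b.tolist() for b in model.bags],
            "oob_votes": model.oob_votes.tolist(),
        }
    elif isinstance(model, KNNModel):
        payload = {
            "kind": "knn", "k": model.k, "ids": model.ids,
            "X": model.X.tolist(), "y": model.y.tolist(),
        }
    elif isinstance(model, C45Model):
        payload = {
            "kind": "c45", "pruning_confidence": model.pruning_confidence,
            "feature_names": model.feature_names,
            "root": _c45_to_obj(model.root),
        }
    elif isinstance(model, SVMModel):
        payload = {
            "kind": "svm", "sigma": model.sigma, "C": model.C, "b": model.b,
            "alpha": model.alpha.tolist(), "X": model.X.tolist(),
            "y": model.y.tolist(), "feature_names": model.feature_names,
        }
    else:
        raise TypeError(f"unknown model type {type(model)!r}")
    payload["format_version"] = FORMAT_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    kind = d["kind"]
    if kind == "random_forest":
        return RandomForestModel(
            d["m_try"], d["n_tree"],
            [_tree_from_obj(t) for t in d["trees"]],
            [np.asarray(b) for b in d["bags"]],
            np.asarray(d["oob_votes"]),
            d["feature_names"], d["seed"],
        )
    if kind == "knn":
        return KNNModel(d["k"], np.asarray(d["X"]), np.asarray(d["y"]), d["ids"])
    if kind == "c45":
        return C45Model(_c45_from_obj(d["root"]), d["pruning_confidence"],
                        d["feature_names"])
    if kind == "svm":
        return SVMModel(d["sigma"], d["C"], np.asarray(d["alpha"]), d["b"],
                        np.asarray(d["X"]), np.asarray(d["y"]),
                        d["feature_names"])
    raise ValueError(f"unknown model kind {kind!r}")
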