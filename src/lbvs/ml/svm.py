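"""Soft-margin SVM with a Gaussian (RBF) kernel, trained by SMO.

Kernel parameterized by the width sigma: k(x, y) = exp(-||x-y||^2 / (2 sigma^2)),
so k(x, x) = 1.  A gamma-form (exp(-gamma ||x-y||^2)) is accepted via
``gamma=`` for interoperability.  The dual problem is solved with
sequential minimal optimization to a stated KKT tolerance; an iteration
cap turns non-convergence into a loud error instead of a silent bad model.
The prediction score is a logistic map of the decision value — monotone in
the margin, used only for ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset
from .forest import PredictionResult


class SVMConvergenceError(RuntimeError):
    pass


@dataclass
class SVMModel:
    sigma: float
    C: float
    alpha: np.ndarray      # dual coefficients (support coefficients)
    b: float
    X: np.ndarray          # training rows (standardized)
    y: np.ndarray
    feature_names: list[str]

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = _rbf(X, self.X, self.sigma)
        return K @ (self.alpha * self.y) + self.b


def _rbf(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (
        (A**2).sum(axis=1)[:, None]
        + (B**2).sum(axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-np.clip(d2, 0.0, None) / (2.0 * sigma**2))


def train_svm(
    train: LabeledDataset,
    sigma: float = 0.2,
    C: float = 1.0,
    gamma: float | None = None,
    tol: float = 1e-3,
    max_iter: int = 200000,
    seed: int = 0,
) -> SVMModel:
    """Fit the dual soft-margin problem with simplified SMO.

    Raises :class:`SVMConvergenceError` if the iteration cap is exhausted
    before the KKT conditions hold at tolerance ``tol``.
    """
    if gamma is not None:
        sigma = math.sqrt(1.0 / (2.0 * gamma))
    if sigma <= 0 or C <= 0:
        raise ValueError("sigma and C must be positive")
    X = train.X.astype(float)
    y = train.y.astype(float)
    n = len(y)
    K = _rbf(X, X, sigma)
    alpha = np.zeros(n)
    b = 0.0
    rng = np.random.default_rng(seed)
    iters = 0
    while True:  # a full pass with no updates means the KKT conditions hold
        changed = 0
        for i in range(n):
            iters += 1
            if iters > max_iter:
                raise SVMConvergenceError(
                    f"SMO did not converge within {max_iter} iterations "
                    f"(sigma={sigma}, C={C})"
                )
            Ei = (alpha * y) @ K[:, i] + b - y[i]
            if (y[i] * Ei < -tol and alpha[i] < C) or (y[i] * Ei > tol and alpha[i] > 0):
                j = int(rng.integers(n - 1))
                if j >= i:
                    j += 1
                Ej = (alpha * y) @ K[:, j] + b - y[j]
                ai_old, aj_old = alpha[i], alpha[j]
                if y[i] != y[j]:
                    L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
                else:
                    L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
                if H - L < 1e-12:
                    continue
                eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
                if eta >= 0:
                    continue
                aj = np.clip(aj_old - y[j] * (Ei - Ej) / eta, L, H)
                if abs(aj - aj_old) < 1e-7:
                    continue
                ai = ai_old + y[i] * y[j] * (aj_old - aj)
                alpha[i], alpha[j] = ai, aj
                b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
                b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
                if 0 < ai < C:
                    b = b1
                elif 0 < aj < C:
                    b = b2
                else:
                    b = 0.5 * (b1 + b2)
                changed += 1
        if changed == 0:
            break
    return SVMModel(sigma, C, alpha, float(b), X.copy(), train.y.copy(),
                    list(train.feature_names))


def svm_predict(model: SVMModel, X: np.ndarray, ids=None) -> list[PredictionResult]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
    f = model.decision(X)
    out = []
    for mol_id, fv in zip(ids, f):
        label = 1 if fv > 0 else -1
        score = 1.0 / (1.0 + math.exp(-float(fv)))
        out.append(PredictionResult(mol_id, label, score))
    return out
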