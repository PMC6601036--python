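import itertools
import math

import numpy as np
import pytest

from lbvs.ml import (
    LabeledDataset,
    c45_predict,
    knn_predict,
    standardize_features,
    svm_predict,
    train_c45,
    train_knn,
    train_svm,
)
from lbvs.ml.c45 import gain_ratio


def dataset(X, y, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return LabeledDataset(
        [f"m{i}" for i in range(len(y))], X, np.asarray(y, int), names
    )


class TestKNN:
    def test_k1_training_point_returns_own_label(self):
        d = dataset([[0.0], [1.0], [2.0]], [1, -1, 1])
        model = train_knn(d, k=1)
        for x, label in zip(d.X, d.y):
            assert knn_predict(model, [x])[0].label == label

    def test_k3_majority_and_score(self):
        d = dataset([[0.0], [0.1], [0.2], [5.0]], [1, 1, -1, -1])
        model = train_knn(d, k=3)
        res = knn_predict(model, [[0.05]])[0]
        assert res.label == 1
        assert res.score == pytest.approx(2 / 3)

    def test_k_equals_n_gives_global_majority(self):
        d = dataset([[i] for i in range(7)], [1, 1, 1, 1, -1, -1, -1])
        model = train_knn(d, k=7)
        for q in (-10.0, 0.0, 10.0):
            assert knn_predict(model, [[q]])[0].label == 1

    def test_vote_tie_goes_to_nearest_neighbor(self):
        d = dataset([[0.0], [1.0]], [-1, 1])
        model = train_knn(d, k=2)
        assert knn_predict(model, [[0.1]])[0].label == -1
        assert knn_predict(model, [[0.9]])[0].label == 1

    def test_invalid_k(self):
        d = dataset([[0.0], [1.0]], [1, -1])
        with pytest.raises(ValueError):
            train_knn(d, k=0)
        with pytest.raises(ValueError):
            train_knn(d, k=3)

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.neighbors")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, 1, -1)
        d = dataset(X, y)
        model = train_knn(d, k=5)
        ref = sk.KNeighborsClassifier(n_neighbors=5).fit(X, y)
        Q = rng.normal(size=(25, 3))
        mine = [p.label for p in knn_predict(model, Q)]
        assert np.array_equal(mine, ref.predict(Q))


class TestC45:
    def test_perfect_single_feature_gives_depth_one(self):
        d = dataset([[0.0], [0.2], [0.9], [1.1]], [-1, -1, 1, 1])
        model = train_c45(d)
        root = model.root
        assert not root.is_leaf
        assert root.left.is_leaf and root.right.is_leaf
        preds = [p.label for p in c45_predict(model, d.X)]
        assert np.array_equal(preds, d.y)

    def test_uninformative_split_has_zero_gain_ratio(self):
        y01 = np.array([1, 0, 1, 0])
        go_left = np.array([True, True, False, False])  # 1:1 on both sides
        assert gain_ratio(y01, go_left) == 0.0

    def test_best_split_matches_exhaustive_enumeration(self):
        # 8-row, 2-feature hand table
        X = np.array([
            [1.0, 5.0], [2.0, 1.0], [3.0, 4.0], [4.0, 2.0],
            [5.0, 8.0], [6.0, 3.0], [7.0, 9.0], [8.0, 7.0],
        ])
        y = np.array([-1, -1, -1, 1, -1, 1, 1, 1])
        y01 = (y == 1).astype(int)

        best_gr, best = -1.0, None
        for f in range(2):
            for lo, hi in itertools.pairwise(sorted(set(X[:, f]))):
                thr = (lo + hi) / 2
                gr = gain_ratio(y01, X[:, f] <= thr)
                if gr > best_gr + 1e-12:
                    best_gr, best = gr, (f, thr)

        model = train_c45(dataset(X, y), pruning_confidence=0.25)
        assert (model.root.feature, model.root.threshold) == best

    def test_pruning_collapses_noise_subtrees(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 1))
        y = np.where(rng.random(60) < 0.5, 1, -1)  # pure noise
        pruned = train_c45(dataset(X, y), pruning_confidence=0.25)

        def count(node):
            return 1 if node.is_leaf else 1 + count(node.left) + count(node.right)

        # near-1 confidence keeps the optimistic (unpruned) tree
        lax = train_c45(dataset(X, y), pruning_confidence=0.999)
        assert count(pruned.root) < count(lax.root)

    def test_single_class_rejected(self):
        d = dataset([[0.0], [1.0]], [1, 1])
        with pytest.raises(ValueError):
            train_c45(d)


class TestSVM:
    def xor_data(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        return dataset(X, y)

    def test_xor_separable_with_narrow_rbf(self):
        d = self.xor_data()
        model = train_svm(d, sigma=0.2, C=1e3)
        preds = [p.label for p in svm_predict(model, d.X)]
        assert np.array_equal(preds, d.y)

    def test_kernel_self_similarity_is_one(self):
        from lbvs.ml.svm import _rbf

        X = np.random.default_rng(3).normal(size=(5, 4))
        K = _rbf(X, X, sigma=0.7)
        assert np.allclose(np.diag(K), 1.0)

    def test_two_point_margin_is_equidistant(self):
        d = dataset([[-1.0], [1.0]], [-1, 1])
        model = train_svm(d, sigma=1.0, C=10.0)
        # decision boundary midway between the two points by symmetry
        assert model.decision(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-6)
        assert model.decision(np.array([[0.5]]))[0] > 0
        assert model.decision(np.array([[-0.5]]))[0] < 0

    def test_duplicate_rows_leave_decision_nearly_unchanged(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        base = dataset(X, y)
        dup = dataset(np.vstack([X, X]), np.concatenate([y, y]))
        m1 = train_svm(base, sigma=1.0, C=5.0)
        m2 = train_svm(dup, sigma=1.0, C=5.0)
        Q = rng.normal(size=(20, 2))
        assert np.array_equal(
            np.sign(m1.decision(Q)), np.sign(m2.decision(Q))
        )

    def test_agrees_with_reference_solver(self):
        svm_mod = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] + X[:, 1] > 0, 1, -1)
        d = dataset(X, y)
        sigma, C = 1.0, 2.0
        mine = train_svm(d, sigma=sigma, C=C)
        ref = svm_mod.SVC(kernel="rbf", gamma=1.0 / (2 * sigma**2), C=C).fit(X, y)
        Q = rng.normal(size=(40, 2))
        agree = np.mean(np.sign(mine.decision(Q)) == ref.predict(Q))
        assert agree >= 0.95

    def test_invalid_parameters(self):
        d = self.xor_data()
        with pytest.raises(ValueError):
            train_svm(d, sigma=-1.0)
        with pytest.raises(ValueError):
            train_svm(d, sigma=0.2, C=0.0)

    def test_score_monotone_in_margin(self):
        d = self.xor_data()
        model = train_svm(d, sigma=0.2, C=100.0)
        f = model.decision(d.X)
        s = np.array([p.score for p in svm_predict(model, d.X)])
        assert np.array_equal(np.argsort(f), np.argsort(s))


class TestCrossModelInvariants:
    def test_predictions_invariant_under_feature_permutation(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 4))
        y = np.where(X[:, 1] > 0, 1, -1)
        Q = rng.normal(size=(15, 4))
        perm = [3, 1, 0, 2]
        d1 = dataset(X, y)
        d2 = dataset(X[:, perm], y, names=[f"f{j}" for j in perm])

        k1 = [p.label for p in knn_predict(train_knn(d1, 3), Q)]
        k2 = [p.label for p in knn_predict(train_knn(d2, 3), Q[:, perm])]
        assert k1 == k2

        s1 = [p.label for p in svm_predict(train_svm(d1, sigma=1.0, C=2.0), Q)]
        s2 = [p.label for p in svm_predict(train_svm(d2, sigma=1.0, C=2.0), Q[:, perm])]
        assert s1 == s2

    def test_knn_invariant_to_affine_restandardization(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        Q = rng.normal(size=(10, 3))
        d = dataset(X, y)
        scaled = dataset(X * [2.0, 5.0, 0.5] + [1.0, -3.0, 0.0], y)
        tr1, _ = standardize_features(d)
        tr2, _ = standardize_features(scaled)
        a = [p.label for p in knn_predict(train_knn(tr1, 3),
                                          (Q - d.X.mean(0)) / d.X.std(0))]
        b = [p.label for p in knn_predict(
            train_knn(tr2, 3),
            (Q * [2.0, 5.0, 0.5] + [1.0, -3.0, 0.0] - scaled.X.mean(0))
            / scaled.X.std(0))]
        assert a == b
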