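"""Random-Tree / C4.5 induction, prediction conventions and serialization."""

import math

import numpy as np
import pytest

import pgpscreen as pg
from pgpscreen import (C45Classifier, RandomTreeClassifier, TreeConfig,
                       train_c45, train_random_tree, tree_descriptors)
from pgpscreen.trees import predict

from conftest import make_dataset


def brute_force_best_gain(X, y, min_child=1):
    """Independent exhaustive information-gain search over all midpoints."""
    def entropy(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        p = sum(labels) / n
        return -sum(q * math.log(q) for q in (p, 1 - p) if q > 0)

    n = len(y)
    parent = entropy(y)
    best = (None, None, 0.0)
    for j in range(X.shape[1]):
        vals = sorted(set(X[:, j]))
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2
            left = [y[i] for i in range(n) if X[i, j] < thr]
            right = [y[i] for i in range(n) if X[i, j] >= thr]
            if len(left) < min_child or len(right) < min_child:
                continue
            gain = parent - (len(left) / n) * entropy(left) \
                - (len(right) / n) * entropy(right)
            if gain > best[2] + 1e-12:
                best = (j, thr, gain)
    return best


class TestRandomTree:
    def test_recovers_planted_rule_as_depth_one_tree(self, small_noiseless):
        """K = all descriptors, noiseless single-rule data: one split, at the
        planted descriptor's calibrated threshold."""
        n_desc = small_noiseless.table.shape[1]
        tree = train_random_tree(small_noiseless, "inhibition",
                                 TreeConfig(k_attributes=n_desc, seed=7))
        (desc_idx, threshold, _), = \
            small_noiseless.meta["planted_rules"]["inhibition"]
        planted_name = small_noiseless.table.descriptor_names[desc_idx]
        assert tree_descriptors(tree) == {planted_name}
        root = tree.root
        assert root.left.is_leaf and root.right.is_leaf
        assert root.threshold == pytest.approx(threshold)

    def test_pure_input_rejected_by_training_contract(self):
        data = make_dataset([[1.0], [2.0], [3.0]], [1, 1, 1])
        with pytest.raises(ValueError):
            train_random_tree(data, "inhibition", TreeConfig(k_attributes=1))

    def test_single_class_estimator_gives_single_leaf(self):
        est = RandomTreeClassifier(k_attributes=1).fit([[1.0], [2.0]], ["Y", "Y"])
        assert est.tree_.root.is_leaf

    def test_deterministic(self, small_noiseless):
        config = TreeConfig(k_attributes=4, seed=11)
        t1 = train_random_tree(small_noiseless, "efflux", config)
        t2 = train_random_tree(small_noiseless, "efflux", config)
        assert t1.to_dict() == t2.to_dict()

    def test_k_exceeding_descriptor_count_rejected(self, small_noiseless):
        n_desc = small_noiseless.table.shape[1]
        with pytest.raises(ValueError):
            train_random_tree(small_noiseless, "inhibition",
                              TreeConfig(k_attributes=n_desc + 1))

    def test_full_k_matches_greedy_bruteforce_root(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        y = (X[:, 1] > 0).astype(int)
        y[0] ^= 1  # one contradiction so the tree has depth > 1
        data = make_dataset(X, y)
        tree = train_random_tree(data, "inhibition",
                                 TreeConfig(k_attributes=3, seed=2))
        j, thr, gain = brute_force_best_gain(X, y)
        assert tree.root.feature == j
        assert tree.root.threshold == pytest.approx(thr)

    def test_unpruned_tree_reaches_pure_leaves(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 4))
        y = ((X[:, 0] + X[:, 2] > 0)).astype(int)
        data = make_dataset(X, y)
        tree = train_random_tree(data, "inhibition",
                                 TreeConfig(k_attributes=4, seed=5))
        est = RandomTreeClassifier(k_attributes=4, seed=5).fit(
            data.table.data, data.label_vector("inhibition"))
        preds = est.predict(data.table.data)
        assert (preds == data.label_vector("inhibition")).all()


class TestC45:
    def test_noiseless_separable_keeps_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = (X[:, 0] > 0.2).astype(int)
        data = make_dataset(X, y)
        tree = train_c45(data, "inhibition",
                         TreeConfig(algorithm="c45", min_instances=1))
        correct = sum(predict(tree, data.table.row(c)).label ==
                      data.label("inhibition", c).value
                      for c in data.table.compound_ids)
        assert correct == 20

    def test_min_instances_n_forces_majority_leaf(self):
        data = make_dataset([[float(i)] for i in range(10)],
                            [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        tree = train_c45(data, "inhibition",
                         TreeConfig(algorithm="c45", min_instances=10))
        assert tree.root.is_leaf
        assert predict(tree, {"D1": 0.0}).label == "N"

    def test_min_instances_larger_than_dataset_rejected(self):
        data = make_dataset([[0.0], [1.0]], [0, 1])
        with pytest.raises(ValueError):
            train_c45(data, "inhibition",
                      TreeConfig(algorithm="c45", min_instances=3))

    def test_pruning_shrinks_noisy_tree(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] > 0).astype(int)
        flip = rng.random(40) < 0.2
        data = make_dataset(X, y ^ flip)
        unpruned = C45Classifier(confidence_factor=0.9999, min_instances=1).fit(
            data.table.data, data.label_vector("inhibition"))
        pruned = C45Classifier(confidence_factor=0.05, min_instances=1).fit(
            data.table.data, data.label_vector("inhibition"))
        assert pruned.tree_.n_leaves() <= unpruned.tree_.n_leaves()

    def test_reduced_error_pruning_runs(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4))
        y = (X[:, 1] > 0).astype(int)
        data = make_dataset(X, y)
        tree = train_c45(data, "inhibition",
                         TreeConfig(algorithm="c45", num_folds=3, seed=2))
        assert tree.root.total == 30 - 30 // 3  # grown on the non-held-out part


class TestPrediction:
    def test_laplace_probability_single_leaf(self):
        est = RandomTreeClassifier(k_attributes=1).fit(
            [[0.0]] * 5, ["Y"] * 5)
        pred = est.tree_.predict_row({"x0": 1.0})
        assert pred.label == "Y"
        assert pred.y_probability == pytest.approx(6 / 7)

    def test_value_at_threshold_routes_right(self):
        data = make_dataset([[0.0], [2.0]], [0, 1])
        tree = train_random_tree(data, "inhibition", TreeConfig(k_attributes=1))
        assert tree.root.threshold == 1.0
        assert predict(tree, {"D1": 1.0}).label == "Y"  # >= goes right
        assert predict(tree, {"D1": 0.99}).label == "N"

    def test_tie_leaf_predicts_n_with_flag(self):
        from pgpscreen.trees import DecisionTree, Node
        tree = DecisionTree(Node(2, 2), ["D1"], TreeConfig())
        pred = predict(tree, {"D1": 0.0})
        assert pred.label == "N" and pred.tie
        assert pred.y_probability == pytest.approx(0.5)

    def test_missing_descriptor_named_in_error(self):
        data = make_dataset([[0.0], [2.0]], [0, 1])
        tree = train_random_tree(data, "inhibition", TreeConfig(k_attributes=1))
        with pytest.raises(KeyError, match="D1"):
            predict(tree, {"other": 1.0})


class TestTreeUtilities:
    def test_descriptor_sets(self, small_noiseless):
        from pgpscreen.trees import DecisionTree, Node
        leaf_tree = DecisionTree(Node(3, 0), ["D1"], TreeConfig())
        assert tree_descriptors(leaf_tree) == set()
        tree = train_random_tree(small_noiseless, "inhibition",
                                 TreeConfig(k_attributes=20, seed=7))
        assert tree_descriptors(tree) == {"D0001"}

    def test_json_round_trip(self, small_noiseless, tmp_path):
        tree = train_random_tree(small_noiseless, "efflux",
                                 TreeConfig(k_attributes=6, seed=4))
        tree.save(tmp_path / "m.json")
        again = pg.DecisionTree.load(tmp_path / "m.json")
        assert again.to_dict() == tree.to_dict()
        row = small_noiseless.table.row(small_noiseless.table.compound_ids[0])
        assert predict(again, row) == predict(tree, row)

    def test_render_mentions_descriptor_and_threshold(self, small_noiseless):
        tree = train_random_tree(small_noiseless, "inhibition",
                                 TreeConfig(k_attributes=20, seed=7))
        text = tree.render()
        assert "D0001" in text and ">=" in text


def test_gain_matches_bruteforce_on_every_node():
    """Every split chosen on a small instance maximises brute-force info gain
    over the node's own samples (full-K random tree = greedy tree)."""
    rng = np.random.default_rng(12)
    X = rng.normal(size=(12, 3))
    y = ((X[:, 0] > 0) & (X[:, 2] < 0.5)).astype(int)
    data = make_dataset(X, y)
    tree = train_random_tree(data, "inhibition", TreeConfig(k_attributes=3, seed=1))

    def walk(node, rows):
        if node.is_leaf:
            return
        Xs, ys = X[rows], y[rows]
        j, thr, gain = brute_force_best_gain(Xs, ys)
        assert node.feature == j
        assert node.threshold == pytest.approx(thr)
        mask = X[rows, node.feature] < node.threshold
        walk(node.left, rows[mask])
        walk(node.right, rows[~mask])

    walk(tree.root, np.arange(12))
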