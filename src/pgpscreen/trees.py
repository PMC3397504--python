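"""Decision-tree induction for binary QSAR classification.

Two tree growers are provided, modelled on the classic WEKA learners:

* :class:`RandomTreeClassifier` — at every node, K descriptors are sampled
  uniformly without replacement and the best midpoint binary split by
  information gain among them is taken.  No depth limit; growth stops at
  purity, at zero gain, or when a child would fall below the minimum leaf
  weight.  Different seeds S give different trees, which is what the
  consensus layer exploits.
* :class:`C45Classifier` — grows by gain ratio, then prunes either with a
  pessimistic binomial upper confidence bound on the leaf error rates
  (confidence factor CF, default 0.25) or by reduced-error pruning against
  a held-out 1/num_folds fraction.

Splits are binary on numeric descriptors: ``value < threshold`` goes left,
``value >= threshold`` goes right, with thresholds at midpoints between
consecutive distinct observed values.  Ties in gain are broken toward the
lower descriptor index and lower threshold so that training is fully
deterministic given the data and the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta
from sklearn.base import BaseEstimator, ClassifierMixin

from .core_io import LabeledDataset

_EPS = 1e-12


@dataclass
class TreeConfig:
    """Hyperparameters for a single tree model.

    ``algorithm`` selects which parameter block is honoured:
    ``random_tree`` uses ``k_attributes`` (K), ``seed`` (S) and
    ``min_leaf_weight``; ``c45`` uses ``confidence_factor``,
    ``min_instances`` and optionally ``num_folds`` (reduced-error pruning).
    There is no maximum depth.
    """

    algorithm: str = "random_tree"
    k_attributes: int = 1
    seed: int = 1
    min_leaf_weight: int = 1
    confidence_factor: float = 0.25
    min_instances: int = 2
    num_folds: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("random_tree", "c45"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.k_attributes < 1:
            raise ValueError("k_attributes must be >= 1")

    @property
    def name(self) -> str:
        if self.algorithm == "random_tree":
            return f"RT(S{self.seed} K{self.k_attributes})"
        return f"C4.5(CF{self.confidence_factor} M{self.min_instances})"


@dataclass
class Node:
    """One tree node; leaves carry the training class counts."""

    n_y: int
    n_n: int
    feature: int | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def total(self) -> int:
        return self.n_y + self.n_n


@dataclass(frozen=True)
class TreePrediction:
    label: str
    y_probability: float
    tie: bool = False


@dataclass
class DecisionTree:
    """A trained binary decision tree over named descriptors."""

    root: Node
    descriptor_names: list[str]
    config: TreeConfig
    training_ids: list[str] = field(default_factory=list)

    def _route(self, vector) -> Node:
        node = self.root
        while not node.is_leaf:
            name = self.descriptor_names[node.feature]
            try:
                value = float(vector[name])
            except (KeyError, IndexError):
                raise KeyError(f"compound vector is missing descriptor {name!r}") from None
            node = node.left if value < node.threshold else node.right
        return node

    def predict_row(self, vector) -> TreePrediction:
        """Classify one compound given a name-indexed descriptor vector.

        The leaf's majority class is returned (ties go to N, flagged) with a
        Laplace-corrected Y probability (n_Y + 1) / (n + 2).
        """
        leaf = self._route(vector)
        prob = (leaf.n_y + 1) / (leaf.total + 2)
        if leaf.n_y > leaf.n_n:
            return TreePrediction("Y", prob)
        return TreePrediction("N", prob, tie=leaf.n_y == leaf.n_n)

    def descriptors(self) -> set[str]:
        """Distinct descriptor names tested anywhere in the tree."""
        names: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                names.add(self.descriptor_names[node.feature])
                stack.extend([node.left, node.right])
        return names

    def n_leaves(self) -> int:
        stack, n = [self.root], 0
        while stack:
            node = stack.pop()
            if node.is_leaf:
                n += 1
            else:
                stack.extend([node.left, node.right])
        return n

    # -- serialization -----------------------------------------------------
    def _node_dict(self, node: Node) -> dict:
        if node.is_leaf:
            return {"leaf": True, "n_y": node.n_y, "n_n": node.n_n}
        return {
            "leaf": False,
            "n_y": node.n_y,
            "n_n": node.n_n,
            "descriptor": self.descriptor_names[node.feature],
            "threshold": node.threshold,
            "left": self._node_dict(node.left),
            "right": self._node_dict(node.right),
        }

    def to_dict(self) -> dict:
        return {
            "descriptor_names": self.descriptor_names,
            "config": vars(self.config).copy(),
            "training_ids": self.training_ids,
            "root": self._node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DecisionTree":
        names = list(payload["descriptor_names"])
        index = {n: i for i, n in enumerate(names)}

        def build(d: dict) -> Node:
            if d["leaf"]:
                return Node(d["n_y"], d["n_n"])
            return Node(
                d["n_y"], d["n_n"], feature=index[d["descriptor"]],
                threshold=float(d["threshold"]),
                left=build(d["left"]), right=build(d["right"]),
            )

        return cls(
            root=build(payload["root"]),
            descriptor_names=names,
            config=TreeConfig(**payload["config"]),
            training_ids=list(payload.get("training_ids", [])),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "DecisionTree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def render(self) -> str:
        """Indented text rendering, e.g. ``XLogP >= 1.6``-style branches."""
        lines: list[str] = []

        def walk(node: Node, depth: int) -> None:
            pad = "  " * depth
            if node.is_leaf:
                label = "Y" if node.n_y > node.n_n else "N"
                lines.append(f"{pad}-> {label} ({node.n_y}Y/{node.n_n}N)")
                return
            name = self.descriptor_names[node.feature]
            lines.append(f"{pad}{name} < {node.threshold:g}:")
            walk(node.left, depth + 1)
            lines.append(f"{pad}{name} >= {node.threshold:g}:")
            walk(node.right, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# split search


def _entropy(n_y: np.ndarray, n_n: np.ndarray) -> np.ndarray:
    """Binary entropy (nats) of count pairs, 0 for empty groups."""
    total = n_y + n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, n_y / np.maximum(total, 1), 0.0)
        h = -(np.where(p > 0, p * np.log(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log(1 - p), 0.0))
    return np.where(total > 0, h, 0.0)


def _best_split(X: np.ndarray, y: np.ndarray, candidates: Sequence[int],
                min_child: int, use_gain_ratio: bool):
    """Best (feature, threshold, gain) over candidate features, or None.

    Thresholds are midpoints between consecutive distinct sorted values;
    both children must hold at least ``min_child`` samples and the split's
    information gain must be positive.  Candidates are scanned in ascending
    index order and thresholds in ascending order, so the first strict
    improvement wins: ties resolve to the lower index, lower threshold.
    """
    n = len(y)
    parent_h = float(_entropy(np.array([y.sum()]), np.array([n - y.sum()]))[0])
    best = None
    best_score = _EPS
    for j in sorted(candidates):
        order = np.argsort(X[:, j], kind="stable")
        v = X[order, j]
        yo = y[order]
        cum_y = np.cumsum(yo)
        # boundary after position i-1 → left has i samples
        sizes = np.arange(1, n)
        distinct = v[1:] > v[:-1]
        valid = distinct & (sizes >= min_child) & (n - sizes >= min_child)
        if not valid.any():
            continue
        left_y = cum_y[:-1]
        left_n = sizes - left_y
        right_y = cum_y[-1] - left_y
        right_n = (n - sizes) - right_y
        h_left = _entropy(left_y, left_n)
        h_right = _entropy(right_y, right_n)
        gain = parent_h - (sizes / n) * h_left - ((n - sizes) / n) * h_right
        if use_gain_ratio:
            p = sizes / n
            split_info = -(p * np.log(p) + (1 - p) * np.log(1 - p))
            score = np.where(gain > _EPS, gain / split_info, 0.0)
        else:
            score = gain
        score = np.where(valid & (gain > _EPS), score, -np.inf)
        i = int(np.argmax(score))
        if score[i] > best_score + _EPS:
            best_score = float(score[i])
            threshold = (v[i] + v[i + 1]) / 2.0
            best = (j, threshold, float(gain[i]))
    return best


def _counts(y: np.ndarray) -> tuple[int, int]:
    s = int(y.sum())
    return s, len(y) - s


# ---------------------------------------------------------------------------
# estimators


class _TreeEstimator(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the two tree learners."""

    classes_: np.ndarray

    def _validate(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(values.shape[1])]
        y = np.asarray(y)
        if y.dtype.kind in "ifb":
            y01 = y.astype(int)
        else:
            y01 = (y == "Y").astype(int)
        if values.shape[0] != len(y01):
            raise ValueError("X and y length mismatch")
        if values.shape[0] < 1:
            raise ValueError("empty training set")
        return values, y01, names

    def _as_matrix(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        arr = np.asarray(X, dtype=float)
        return arr, [f"x{i}" for i in range(arr.shape[1])]

    def predict(self, X):
        arr, names = self._as_matrix(X)
        cols = {n: i for i, n in enumerate(names)}
        out = []
        for row in arr:
            vec = {n: row[cols[n]] for n in self.tree_.descriptor_names if n in cols}
            missing = set(self.tree_.descriptors()) - set(vec)
            if missing:
                raise KeyError(f"missing descriptors: {sorted(missing)}")
            out.append(self.tree_.predict_row(vec).label)
        return np.array(out)

    def predict_proba(self, X):
        arr, names = self._as_matrix(X)
        cols = {n: i for i, n in enumerate(names)}
        probs = []
        for row in arr:
            vec = {n: row[cols[n]] for n in self.tree_.descriptor_names if n in cols}
            p = self.tree_.predict_row(vec).y_probability
            probs.append([1 - p, p])
        return np.array(probs)


class RandomTreeClassifier(_TreeEstimator):
    """Random tree considering K randomly chosen descriptors at each node.

    Attribute sampling at a node draws from a dedicated child of the seeded
    generator, keyed by the node's pre-order visit index, so the tree is a
    deterministic function of (data, K, seed) and does not depend on row
    insertion order.
    """

    def __init__(self, k_attributes: int = 1, seed: int = 1,
                 min_leaf_weight: int = 1):
        self.k_attributes = k_attributes
        self.seed = seed
        self.min_leaf_weight = min_leaf_weight

    def fit(self, X, y):
        values, y01, names = self._validate(X, y)
        n_features = values.shape[1]
        if not 1 <= self.k_attributes <= n_features:
            raise ValueError(
                f"k_attributes={self.k_attributes} outside [1, {n_features}]"
            )
        counter = [0]

        def grow(rows: np.ndarray) -> Node:
            node_idx = counter[0]
            counter[0] += 1
            yy = y01[rows]
            n_y, n_n = _counts(yy)
            if n_y == 0 or n_n == 0:
                return Node(n_y, n_n)
            rng = np.random.default_rng([max(self.seed, 0), node_idx])
            cand = rng.permutation(n_features)[: self.k_attributes]
            split = _best_split(values[rows], yy, cand,
                                max(self.min_leaf_weight, 1), use_gain_ratio=False)
            if split is None:
                return Node(n_y, n_n)
            j, thr, _ = split
            mask = values[rows, j] < thr
            return Node(n_y, n_n, feature=j, threshold=thr,
                        left=grow(rows[mask]), right=grow(rows[~mask]))

        config = TreeConfig(algorithm="random_tree", k_attributes=self.k_attributes,
                            seed=self.seed, min_leaf_weight=self.min_leaf_weight)
        self.tree_ = DecisionTree(grow(np.arange(len(y01))), names, config)
        self.feature_names_in_ = np.array(names)
        self.classes_ = np.array(["N", "Y"])
        return self


def _pessimistic_errors(e: int, n: int, cf: float) -> float:
    """Expected errors n·U_cf(e, n) with U the binomial upper confidence bound."""
    if n == 0:
        return 0.0
    if e >= n:
        return float(n)
    return float(n) * float(beta.ppf(1.0 - cf, e + 1, n - e))


class C45Classifier(_TreeEstimator):
    """C4.5-style learner: gain-ratio growth plus pruning.

    With ``num_folds`` unset, pruning is pessimistic: a subtree is collapsed
    to a leaf when the leaf's upper-confidence-bound error estimate (at
    ``confidence_factor``) does not exceed the sum of its leaves' estimates.
    With ``num_folds`` set, a 1/num_folds fraction is held out (seeded
    shuffle), the tree is grown on the remainder and subtrees are collapsed
    whenever that does not increase held-out errors.  Subtree raising is not
    performed.
    """

    def __init__(self, confidence_factor: float = 0.25, min_instances: int = 2,
                 num_folds: int | None = None, seed: int = 1):
        self.confidence_factor = confidence_factor
        self.min_instances = min_instances
        self.num_folds = num_folds
        self.seed = seed

    def fit(self, X, y):
        values, y01, names = self._validate(X, y)
        n = len(y01)
        if self.min_instances > n:
            raise ValueError("min_instances exceeds the training-set size")
        if self.num_folds:
            rng = np.random.default_rng(max(self.seed, 0))
            perm = rng.permutation(n)
            n_hold = max(n // int(self.num_folds), 1)
            hold, grow_rows = perm[:n_hold], perm[n_hold:]
            if len(grow_rows) == 0:
                raise ValueError("num_folds leaves no data to grow on")
        else:
            hold, grow_rows = np.array([], dtype=int), np.arange(n)

        def grow(rows: np.ndarray) -> Node:
            yy = y01[rows]
            n_y, n_n = _counts(yy)
            if n_y == 0 or n_n == 0 or len(rows) < 2 * self.min_instances:
                return Node(n_y, n_n)
            split = _best_split(values[rows], yy, range(values.shape[1]),
                                max(self.min_instances, 1), use_gain_ratio=True)
            if split is None:
                return Node(n_y, n_n)
            j, thr, _ = split
            mask = values[rows, j] < thr
            return Node(n_y, n_n, feature=j, threshold=thr,
                        left=grow(rows[mask]), right=grow(rows[~mask]))

        root = grow(grow_rows)
        if self.num_folds:
            root = self._reduced_error_prune(root, values[hold], y01[hold])
        else:
            root = self._pessimistic_prune(root)
        config = TreeConfig(algorithm="c45", confidence_factor=self.confidence_factor,
                            min_instances=self.min_instances,
                            num_folds=self.num_folds, seed=self.seed)
        self.tree_ = DecisionTree(root, names, config)
        self.feature_names_in_ = np.array(names)
        self.classes_ = np.array(["N", "Y"])
        return self

    def _pessimistic_prune(self, node: Node) -> Node:
        if node.is_leaf:
            return node
        node.left = self._pessimistic_prune(node.left)
        node.right = self._pessimistic_prune(node.right)

        def subtree_errors(nd: Node) -> float:
            if nd.is_leaf:
                return _pessimistic_errors(min(nd.n_y, nd.n_n), nd.total,
                                           self.confidence_factor)
            return subtree_errors(nd.left) + subtree_errors(nd.right)

        as_leaf = _pessimistic_errors(min(node.n_y, node.n_n), node.total,
                                      self.confidence_factor)
        if as_leaf <= subtree_errors(node) + 1e-9:
            return Node(node.n_y, node.n_n)
        return node

    def _reduced_error_prune(self, node: Node, X_hold: np.ndarray,
                             y_hold: np.ndarray) -> Node:
        if node.is_leaf or len(y_hold) == 0:
            return node
        mask = X_hold[:, node.feature] < node.threshold
        node.left = self._reduced_error_prune(node.left, X_hold[mask], y_hold[mask])
        node.right = self._reduced_error_prune(node.right, X_hold[~mask], y_hold[~mask])

        def errors(nd: Node, Xh: np.ndarray, yh: np.ndarray) -> int:
            if len(yh) == 0:
                return 0
            if nd.is_leaf:
                pred = 1 if nd.n_y > nd.n_n else 0
                return int((yh != pred).sum())
            m = Xh[:, nd.feature] < nd.threshold
            return errors(nd.left, Xh[m], yh[m]) + errors(nd.right, Xh[~m], yh[~m])

        leaf_pred = 1 if node.n_y > node.n_n else 0
        as_leaf = int((y_hold != leaf_pred).sum())
        if as_leaf <= errors(node, X_hold, y_hold):
            return Node(node.n_y, node.n_n)
        return node


# ---------------------------------------------------------------------------
# functional surface


def _estimator_for(config: TreeConfig):
    if config.algorithm == "random_tree":
        return RandomTreeClassifier(k_attributes=config.k_attributes,
                                    seed=config.seed,
                                    min_leaf_weight=config.min_leaf_weight)
    return C45Classifier(confidence_factor=config.confidence_factor,
                         min_instances=config.min_instances,
                         num_folds=config.num_folds, seed=config.seed)


def _train(data: LabeledDataset, endpoint: str, config: TreeConfig) -> DecisionTree:
    y = data.label_vector(endpoint)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    est = _estimator_for(config).fit(data.table.data, y)
    est.tree_.training_ids = data.table.compound_ids
    return est.tree_


def train_random_tree(data: LabeledDataset, endpoint: str,
                      config: TreeConfig) -> DecisionTree:
    """Train a Random Tree (K attributes per node) on one endpoint."""
    if config.algorithm != "random_tree":
        raise ValueError("config.algorithm must be 'random_tree'")
    return _train(data, endpoint, config)


def train_c45(data: LabeledDataset, endpoint: str, config: TreeConfig) -> DecisionTree:
    """Train a pruned C4.5-style tree on one endpoint."""
    if config.algorithm != "c45":
        raise ValueError("config.algorithm must be 'c45'")
    return _train(data, endpoint, config)


def predict(tree: DecisionTree, compound) -> TreePrediction:
    """Classify a single compound vector (mapping or name-indexed Series)."""
    return tree.predict_row(compound)


def tree_descriptors(tree: DecisionTree) -> set[str]:
    """Distinct descriptors tested on any root-to-leaf path."""
    return tree.descriptors()
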