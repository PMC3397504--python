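"""Class-balanced sphere-exclusion train/test splitting.

The rational split places every test compound within a fixed exclusion
radius of at least one training compound while covering the descriptor
space, and is "driven" so each class contributes exactly ``test_per_class``
compounds to the test set (10 per class for the 59-compound study design,
giving the 39/20 partition).

Algorithm: descriptors are standardized to zero mean / unit variance;
compounds are ordered by decreasing distance from the dataset centroid
(covering the periphery first); the next unassigned compound is taken into
training and all unassigned compounds within radius R of it become test
candidates.  After the sweep, each class keeps the ``test_per_class``
candidates closest to their nearest training compound, returning the rest
to training.  R is found by bisection so every class has enough candidates;
the smallest satisfying radius seen is used.  All orderings break ties on
compound id, so the split is invariant to row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import LabeledDataset, canonical_id


@dataclass(frozen=True)
class SplitConfig:
    test_per_class: int = 10
    standardize: bool = True
    radius_search_tolerance: int = 60
    seed: int = 0


@dataclass
class Split:
    """A training/test partition with the final exclusion radius.

    ``radius`` is in standardized descriptor-space units when
    standardization is on, raw units otherwise.
    """

    training_ids: list[str]
    test_ids: list[str]
    radius: float
    endpoint: str


def _standardized(X: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return X.astype(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd


def _sweep(order: np.ndarray, dist: np.ndarray, radius: float):
    """Sphere-exclusion sweep; returns (training mask, candidate mask)."""
    n = len(order)
    assigned = np.zeros(n, dtype=bool)
    training = np.zeros(n, dtype=bool)
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        training[i] = True
        near = (dist[i] <= radius) & ~assigned
        assigned |= near
    candidates = assigned & ~training
    return training, candidates


def sphere_exclusion_split(data: LabeledDataset, endpoint: str,
                           config: SplitConfig = SplitConfig()) -> Split:
    """Split one endpoint's dataset into training and test sets.

    Raises when a class is too small or when the radius bisection cannot
    reach the exact per-class test counts.
    """
    ids = data.table.compound_ids
    n = len(ids)
    y = data.y01(endpoint)
    tpc = config.test_per_class
    if tpc < 0:
        raise ValueError("test_per_class must be >= 0")
    if 2 * tpc >= n:
        raise ValueError("test set would not leave a smaller training set")
    for cls, count in (("Y", int(y.sum())), ("N", int(n - y.sum()))):
        if count <= tpc:
            raise ValueError(
                f"class {cls} has only {count} compounds; needs more than {tpc}"
            )
    if tpc == 0:
        return Split(list(ids), [], 0.0, endpoint)

    X = _standardized(data.table.values, config.standardize)
    centroid = X.mean(axis=0)
    d_centroid = np.linalg.norm(X - centroid, axis=1)
    # periphery first; ties on compound id for row-order invariance
    order = np.array(sorted(range(n),
                            key=lambda i: (-d_centroid[i], canonical_id(ids[i]))))
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))

    def enough(candidates: np.ndarray) -> bool:
        return (int(y[candidates].sum()) >= tpc
                and int((1 - y)[candidates].sum()) >= tpc)

    lo, hi = 0.0, float(dist.max()) + 1.0
    best_radius = None
    for _ in range(max(config.radius_search_tolerance, 1)):
        mid = (lo + hi) / 2.0
        _, candidates = _sweep(order, dist, mid)
        if enough(candidates):
            best_radius = mid
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-9:
            break
    if best_radius is None:
        _, candidates = _sweep(order, dist, float(dist.max()) + 1.0)
        if enough(candidates):
            best_radius = float(dist.max()) + 1.0
        else:
            raise ValueError(
                "radius search failed to reach the per-class test counts; "
                "increase radius_search_tolerance"
            )
    training, candidates = _sweep(order, dist, best_radius)
    train_idx = np.flatnonzero(training)
    test_idx: list[int] = []
    for cls in (1, 0):
        cand = [i for i in np.flatnonzero(candidates) if y[i] == cls]
        # keep those most similar to the training set
        cand.sort(key=lambda i: (dist[i, train_idx].min(), canonical_id(ids[i])))
        test_idx.extend(cand[:tpc])
        # the remainder returns to training
    test_set = set(test_idx)
    training_ids = [ids[i] for i in range(n) if i not in test_set]
    test_ids = [ids[i] for i in sorted(test_set)]
    return Split(training_ids, test_ids, float(best_radius), endpoint)


def validate_split(split: Split, data: LabeledDataset) -> dict:
    """Diagnostic report for a split; raises on invariant violations."""
    ids = data.table.compound_ids
    canon_all = {canonical_id(c) for c in ids}
    canon_train = {canonical_id(c) for c in split.training_ids}
    canon_test = {canonical_id(c) for c in split.test_ids}
    if (canon_train | canon_test) - canon_all:
        raise ValueError("split contains compounds foreign to the dataset")
    if canon_train & canon_test:
        raise ValueError("training and test sets overlap")
    if canon_train | canon_test != canon_all:
        raise ValueError("split does not cover the dataset")
    y = {canonical_id(c): lab.value
         for c, lab in data.labels[split.endpoint].items()}
    test_y = sum(1 for c in canon_test if y[c] == "Y")
    test_n = len(canon_test) - test_y
    report: dict = {
        "endpoint": split.endpoint,
        "n_training": len(canon_train),
        "n_test": len(canon_test),
        "test_class_counts": {"Y": test_y, "N": test_n},
        "training_class_counts": {
            "Y": sum(1 for c in canon_train if y[c] == "Y"),
            "N": sum(1 for c in canon_train if y[c] == "N"),
        },
        "radius": split.radius,
        "degenerate": len(canon_test) == 0,
    }
    if split.test_ids:
        X = _standardized(data.table.values, True)
        pos = {canonical_id(c): i for i, c in enumerate(ids)}
        train_rows = X[[pos[c] for c in canon_train]]
        nearest = {}
        for c in split.test_ids:
            d = np.linalg.norm(train_rows - X[pos[canonical_id(c)]], axis=1).min()
            nearest[c] = float(d)
        report["nearest_training_distance"] = nearest
        report["max_nearest_training_distance"] = max(nearest.values())
    return report
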