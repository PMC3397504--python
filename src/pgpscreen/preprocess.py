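"""Descriptor pruning and correlation-based feature-subset selection.

The pipeline mirrors standard QSAR descriptor pre-selection: columns with
constant values are dropped, one of every pair of descriptors with absolute
Pearson inter-correlation above 0.95 is dropped, and a compact informative
subset is then chosen by maximising the CFS (correlation-based feature
selection) merit

    merit(S) = k · r̄_cf / sqrt(k + k(k−1) · r̄_ff)

where k = |S|, r̄_cf is the mean absolute descriptor-class correlation
(point-biserial, class coded 0/1) and r̄_ff the mean absolute
descriptor-descriptor correlation within S.  The merit is searched with a
genetic algorithm repeated over several seeds; descriptors are retained by
their selection frequency across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core_io import DescriptorTable, LabeledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Pruning thresholds.

    ``variance_epsilon = 0`` means "constant" is exact equality of all
    values; ``correlation_threshold`` is the absolute Pearson r above which
    one of a descriptor pair is discarded.
    """

    correlation_threshold: float = 0.95
    variance_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")


@dataclass
class FeatureSelectionConfig:
    """GA + CFS subset-search settings.

    Ten runs with distinct seeds are aggregated: a descriptor is kept when
    it appears in at least ``inclusion_fraction`` of the runs' best subsets.
    """

    n_runs: int = 10
    population_size: int = 20
    generations: int = 20
    crossover_prob: float = 0.6
    mutation_prob: float = 0.033
    inclusion_fraction: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for p in (self.crossover_prob, self.mutation_prob, self.inclusion_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


class ConstantFilter(BaseEstimator, TransformerMixin):
    """Drop zero-variance descriptor columns, preserving column order."""

    def __init__(self, variance_epsilon: float = 0.0):
        self.variance_epsilon = variance_epsilon

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[1] == 0:
            raise ValueError("empty descriptor table")
        arr = X.to_numpy(dtype=float)
        spread = arr.max(axis=0) - arr.min(axis=0)
        keep = spread > self.variance_epsilon
        if not keep.any():
            raise ValueError("all descriptor columns are constant")
        self.keep_columns_ = [c for c, k in zip(X.columns, keep) if k]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.keep_columns_]


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Drop the later column of every pair with |Pearson r| above threshold.

    Column pairs are scanned in lexicographic column-index order and the
    later member of an offending pair is dropped, a deterministic greedy
    rule.  Expects constant columns to have been removed first (their
    correlation is undefined).
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        arr = X.to_numpy(dtype=float)
        n_cols = arr.shape[1]
        if n_cols == 0:
            raise ValueError("empty descriptor table")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(np.corrcoef(arr, rowvar=False))
        corr = np.nan_to_num(np.atleast_2d(corr))
        dropped = np.zeros(n_cols, dtype=bool)
        for i in range(n_cols):
            if dropped[i]:
                continue
            over = corr[i, i + 1:] > self.threshold
            dropped[i + 1:] |= over
        self.keep_columns_ = [c for c, d in zip(X.columns, dropped) if not d]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.keep_columns_]


def remove_constant(table: DescriptorTable,
                    config: PreprocessConfig = PreprocessConfig()) -> DescriptorTable:
    """Remove descriptors whose value is constant across all compounds."""
    f = ConstantFilter(config.variance_epsilon).fit(table.data)
    return DescriptorTable(f.transform(table.data))


def correlation_filter(table: DescriptorTable,
                       config: PreprocessConfig = PreprocessConfig()) -> DescriptorTable:
    """Remove descriptors so no surviving pair has |r| above the threshold."""
    f = CorrelationFilter(config.correlation_threshold).fit(table.data)
    return DescriptorTable(f.transform(table.data))


# ---------------------------------------------------------------------------
# CFS merit


def _correlations(X: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(|feature-class r| vector, |feature-feature r| matrix); NaN -> 0."""
    n_cols = X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.corrcoef(np.column_stack([X, y01.astype(float)]), rowvar=False)
    full = np.nan_to_num(full)
    r_cf = np.abs(full[:n_cols, n_cols])
    r_ff = np.abs(full[:n_cols, :n_cols])
    return r_cf, r_ff


def _merit(mask: np.ndarray, r_cf: np.ndarray, r_ff: np.ndarray) -> float:
    k = int(mask.sum())
    if k == 0:
        return 0.0
    idx = np.flatnonzero(mask)
    mean_cf = float(r_cf[idx].mean())
    if k == 1:
        mean_ff = 0.0
    else:
        sub = r_ff[np.ix_(idx, idx)]
        mean_ff = float((sub.sum() - k) / (k * (k - 1)))
    denom = np.sqrt(k + k * (k - 1) * mean_ff)
    return k * mean_cf / denom if denom > 0 else 0.0


def cfs_merit(subset: Iterable[str], data: LabeledDataset, endpoint: str) -> float:
    """CFS merit of a named descriptor subset for one endpoint."""
    names = list(subset)
    if not names:
        raise ValueError("subset must be non-empty")
    all_names = data.table.descriptor_names
    unknown = set(names) - set(all_names)
    if unknown:
        raise KeyError(f"unknown descriptors: {sorted(unknown)}")
    r_cf, r_ff = _correlations(data.table.values, data.y01(endpoint))
    mask = np.isin(np.array(all_names), names)
    return _merit(mask, r_cf, r_ff)


# ---------------------------------------------------------------------------
# GA subset search


def _hill_climb(mask: np.ndarray, r_cf, r_ff) -> tuple[np.ndarray, float]:
    """Single-bit-flip local refinement of a subset until no flip improves."""
    best = _merit(mask, r_cf, r_ff)
    improved = True
    while improved:
        improved = False
        for j in range(len(mask)):
            mask[j] = not mask[j]
            m = _merit(mask, r_cf, r_ff)
            if m > best + 1e-12:
                best = m
                improved = True
            else:
                mask[j] = not mask[j]
    return mask, best


def _ga_run(r_cf: np.ndarray, r_ff: np.ndarray,
            config: FeatureSelectionConfig, seed: int) -> np.ndarray:
    """One GA optimisation of the CFS merit; returns the best subset mask."""
    rng = np.random.default_rng(seed)
    n = len(r_cf)
    p_init = min(0.5, max(3.0 / n, 0.02))
    pop = rng.random((config.population_size, n)) < p_init
    # make sure no individual is empty
    for ind in pop:
        if not ind.any():
            ind[rng.integers(n)] = True
    fitness = np.array([_merit(ind, r_cf, r_ff) for ind in pop])
    for _ in range(config.generations):
        new_pop = [pop[int(np.argmax(fitness))].copy()]  # elitism
        while len(new_pop) < config.population_size:
            # binary tournament selection
            a, b = rng.integers(config.population_size, size=2)
            p1 = pop[a if fitness[a] >= fitness[b] else b]
            a, b = rng.integers(config.population_size, size=2)
            p2 = pop[a if fitness[a] >= fitness[b] else b]
            if rng.random() < config.crossover_prob:
                cross = rng.random(n) < 0.5  # uniform crossover
                child = np.where(cross, p1, p2)
            else:
                child = p1.copy()
            flip = rng.random(n) < config.mutation_prob
            child = child ^ flip
            if not child.any():
                child[rng.integers(n)] = True
            new_pop.append(child)
        pop = np.array(new_pop)
        fitness = np.array([_merit(ind, r_cf, r_ff) for ind in pop])
    best = pop[int(np.argmax(fitness))].copy()
    best, _ = _hill_climb(best, r_cf, r_ff)
    return best


class CFSSubsetSelector(BaseEstimator, TransformerMixin):
    """GA search of the CFS merit, aggregated over repeated seeded runs.

    Fitted attributes: ``frequencies_`` (per-descriptor selection frequency
    across runs, a pandas Series) and ``selected_features_`` (descriptors at
    or above the inclusion fraction; if that set is empty, the top
    descriptors by frequency up to a floor of five, with a warning).
    """

    def __init__(self, config: FeatureSelectionConfig | None = None):
        self.config = config

    def fit(self, X: pd.DataFrame, y):
        config = self.config or FeatureSelectionConfig()
        y01 = np.asarray(y)
        if y01.dtype.kind not in "ifb":
            y01 = (y01 == "Y").astype(int)
        r_cf, r_ff = _correlations(X.to_numpy(dtype=float), y01)
        seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs)
        hits = np.zeros(X.shape[1])
        for run_seed in seeds:
            hits += _ga_run(r_cf, r_ff, config, int(run_seed))
        freq = hits / config.n_runs
        self.frequencies_ = pd.Series(freq, index=X.columns)
        selected = [c for c, f in self.frequencies_.items()
                    if f >= config.inclusion_fraction]
        if not selected:
            floor = min(5, X.shape[1])
            logger.warning(
                "no descriptor reached inclusion fraction %.2f; "
                "falling back to the top %d by frequency",
                config.inclusion_fraction, floor,
            )
            order = self.frequencies_.sort_values(ascending=False, kind="stable")
            selected = list(order.index[:floor])
            selected = [c for c in X.columns if c in set(selected)]
        self.selected_features_ = selected
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.selected_features_]


def ga_subset_search(data: LabeledDataset, endpoint: str,
                     config: FeatureSelectionConfig | None = None,
                     ) -> tuple[list[str], dict[str, float]]:
    """Select descriptors for one endpoint by repeated GA runs on CFS merit.

    Returns (selected descriptor names, per-descriptor selection frequency).
    """
    sel = CFSSubsetSelector(config).fit(data.table.data, data.label_vector(endpoint))
    return sel.selected_features_, sel.frequencies_.to_dict()
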