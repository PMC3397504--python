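"""Applicability domains, AD-aware consensus voting and the profile screen.

An :class:`ApplicabilityDomain` is the interval of Euclidean distances from
the training-set centroid spanned by the training compounds: a query is
covered when its centroid distance lies within [d_min, d_max] (the literal
``strict_range`` rule) or within [0, d_max] (``zero_to_max``, which also
admits compounds more central than any training compound).  Distances are
computed in each model's own descriptor space, optionally standardized.

A :class:`ConsensusModel` majority-votes the validated member trees whose
domain covers the query; a compound covered by no member is out of domain.
Three endpoint consensus models together classify a compound's
(inhibition, ATPase, efflux) profile — the screen for "true" P-gp
inhibitors (Y/N/N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_io import ClassLabel, DescriptorTable, LabeledDataset, ProfileCategory
from .assay_labeling import classify_profile
from .trees import DecisionTree, TreeConfig, _estimator_for
from .validation import (DEFAULT_GATE, ScoredPrediction, SelectionGate,
                         ValidationReport, loo_cv, passes_selection_gate,
                         report_from_predictions)

logger = logging.getLogger(__name__)


class ApplicabilityDomain(BaseEstimator):
    """Centroid-distance applicability domain of a training set."""

    def __init__(self, standardize: bool = True, mode: str = "strict_range"):
        if mode not in ("strict_range", "zero_to_max"):
            raise ValueError(f"unknown AD mode {mode!r}")
        self.standardize = standardize
        self.mode = mode

    def fit(self, X: pd.DataFrame | DescriptorTable, y=None):
        if isinstance(X, DescriptorTable):
            X = X.data
        if len(X) < 2:
            raise ValueError("applicability domain needs at least 2 compounds")
        arr = X.to_numpy(dtype=float)
        self.descriptor_names_ = [str(c) for c in X.columns]
        self.mean_ = arr.mean(axis=0)
        if self.standardize:
            sd = arr.std(axis=0)
            if (sd == 0).any():
                logger.warning("zero-variance column(s) in AD fit; scale set to 1")
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_ = np.ones(arr.shape[1])
        z = (arr - self.mean_) / self.scale_
        self.centroid_ = z.mean(axis=0)  # zero vector when standardized
        d = np.linalg.norm(z - self.centroid_, axis=1)
        self.d_min_ = float(d.min())
        self.d_max_ = float(d.max())
        return self

    def _vector(self, compound) -> np.ndarray:
        try:
            return np.array([float(compound[name])
                             for name in self.descriptor_names_])
        except (KeyError, IndexError) as exc:
            raise KeyError(f"compound vector missing descriptor: {exc}") from None

    def distance(self, compound) -> float:
        """Euclidean centroid distance of a name-indexed compound vector."""
        z = (self._vector(compound) - self.mean_) / self.scale_
        return float(np.linalg.norm(z - self.centroid_))

    def contains(self, compound, mode: str | None = None) -> bool:
        d = self.distance(compound)
        mode = mode or self.mode
        lo = self.d_min_ if mode == "strict_range" else 0.0
        eps = 1e-9 * (1.0 + self.d_max_)  # guards boundary round-off
        return lo - eps <= d <= self.d_max_ + eps

    def to_dict(self) -> dict:
        return {
            "descriptor_names": self.descriptor_names_,
            "standardize": self.standardize,
            "mode": self.mode,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "centroid": self.centroid_.tolist(),
            "d_min": self.d_min_,
            "d_max": self.d_max_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ApplicabilityDomain":
        ad = cls(standardize=payload["standardize"], mode=payload["mode"])
        ad.descriptor_names_ = list(payload["descriptor_names"])
        ad.mean_ = np.array(payload["mean"])
        ad.scale_ = np.array(payload["scale"])
        ad.centroid_ = np.array(payload["centroid"])
        ad.d_min_ = float(payload["d_min"])
        ad.d_max_ = float(payload["d_max"])
        return ad


def fit_ad(training: DescriptorTable, standardize: bool = True,
           mode: str = "strict_range") -> ApplicabilityDomain:
    """Fit the centroid/min-max distance domain of a training table."""
    return ApplicabilityDomain(standardize=standardize, mode=mode).fit(training)


def in_domain(ad: ApplicabilityDomain, compound, mode: str | None = None) -> bool:
    """Whether a compound's centroid distance lies in the allowed range."""
    return ad.contains(compound, mode=mode)


@dataclass
class ConsensusPrediction:
    label: str  # "Y", "N" or "out_of_domain"
    y_votes: int
    n_votes: int
    covering: int
    tie: bool = False
    mean_y_probability: float | None = None


@dataclass
class ConsensusModel:
    """Validated (tree, applicability domain) members for one endpoint."""

    members: list[tuple[DecisionTree, ApplicabilityDomain]]
    endpoint: str
    member_reports: list[ValidationReport] = field(default_factory=list)
    vote: str = "majority"  # or "average" of Laplace Y-probabilities

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a consensus model needs at least one member")


def consensus_predict(model: ConsensusModel, compound,
                      mode: str | None = None) -> ConsensusPrediction:
    """AD-aware vote of the member trees on one compound vector.

    Only members whose domain covers the compound vote; no covering member
    means out of domain.  A tied vote returns N with the tie flag set
    (conservative for a positive-claim screen).  With ``vote='average'``
    the members' Laplace Y-probabilities are averaged and compared to 0.5,
    which coincides with majority voting for equal-weight binary votes.
    """
    y_votes = n_votes = covering = 0
    probs = []
    for tree, ad in model.members:
        if not ad.contains(compound, mode=mode):
            continue
        covering += 1
        pred = tree.predict_row(compound)
        probs.append(pred.y_probability)
        if pred.label == "Y":
            y_votes += 1
        else:
            n_votes += 1
    if covering == 0:
        return ConsensusPrediction("out_of_domain", 0, 0, 0)
    mean_p = float(np.mean(probs))
    if model.vote == "average":
        label = "Y" if mean_p > 0.5 else "N"
        tie = mean_p == 0.5
    else:
        label = "Y" if y_votes > n_votes else "N"
        tie = y_votes == n_votes
    return ConsensusPrediction(label, y_votes, n_votes, covering, tie, mean_p)


def build_consensus(data: LabeledDataset, endpoint: str,
                    candidate_configs: Sequence[TreeConfig],
                    gate: SelectionGate = DEFAULT_GATE,
                    standardize: bool = True,
                    ad_mode: str = "strict_range") -> ConsensusModel:
    """Train candidates, keep those passing the LOO gate, pair with domains.

    Each selected member is retrained on the full training set and paired
    with the applicability domain of that same training table (the member's
    own descriptor space).  Raises when no candidate passes the gate.
    """
    members, reports = [], []
    y = data.label_vector(endpoint)
    for config in candidate_configs:
        report, _ = loo_cv(data, endpoint, config)
        if not passes_selection_gate(report, gate):
            continue
        est = _estimator_for(config).fit(data.table.data, y)
        est.tree_.training_ids = data.table.compound_ids
        ad = fit_ad(data.table, standardize=standardize, mode=ad_mode)
        members.append((est.tree_, ad))
        reports.append(report)
    if not members:
        raise ValueError(
            f"no candidate model passed the selection gate for {endpoint!r}")
    return ConsensusModel(members, endpoint, member_reports=reports)


def consensus_loo_report(data: LabeledDataset, endpoint: str,
                         model: ConsensusModel,
                         member_predictions: Sequence[Sequence[ScoredPrediction]],
                         ) -> ValidationReport:
    """Pool the members' LOO predictions into a consensus LOO report.

    For every training compound, the members whose domain covers it vote
    with their LOO (held-out) predictions; probabilities average over the
    covering members.  A compound covered by no member is voted by all
    members, flagged.
    """
    by_member = [{p.compound_id: p for p in preds} for preds in member_predictions]
    pooled, flags = [], []
    for cid in data.table.compound_ids:
        row = data.table.row(cid)
        votes, probs = [], []
        for (tree, ad), preds in zip(model.members, by_member):
            if ad.contains(row):
                votes.append(preds[cid])
        if not votes:
            flags.append(f"{cid}: covered by no member; voted by all")
            votes = [preds[cid] for preds in by_member]
        n_y = sum(1 for v in votes if v.pred == "Y")
        label = "Y" if n_y > len(votes) - n_y else "N"
        prob = float(np.mean([v.y_probability for v in votes]))
        pooled.append(ScoredPrediction(cid, data.label(endpoint, cid).value,
                                       label, prob))
    report = report_from_predictions(pooled, model_name=f"consensus[{endpoint}]",
                                     flags=flags)
    return report


@dataclass
class ScreenResult:
    """One compound's consensus endpoint labels and profile category."""

    compound_id: str
    labels: dict[str, str]  # endpoint -> "Y"/"N"/"out_of_domain"
    profile: str            # ProfileCategory value or "undetermined"
    votes: dict[str, tuple[int, int, int]]  # endpoint -> (y, n, covering)

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            **self.labels,
            "profile": self.profile,
            "votes": {e: list(v) for e, v in self.votes.items()},
        }


def true_inhibitor_screen(models: Mapping[str, ConsensusModel],
                          compounds: DescriptorTable,
                          mode: str | None = None) -> list[ScreenResult]:
    """Screen compounds for the Y/N/N "true inhibitor" profile.

    ``models`` maps the three endpoints to their consensus models.  A
    compound's profile is classified only when all three endpoint labels
    are determined; any out-of-domain endpoint leaves it undetermined.
    """
    for endpoint in ("inhibition", "atpase", "efflux"):
        if endpoint not in models:
            raise ValueError(f"missing consensus model for {endpoint!r}")
    results = []
    for cid in compounds.compound_ids:
        row = compounds.row(cid)
        labels, votes = {}, {}
        for endpoint, model in models.items():
            pred = consensus_predict(model, row, mode=mode)
            labels[endpoint] = pred.label
            votes[endpoint] = (pred.y_votes, pred.n_votes, pred.covering)
        if "out_of_domain" in labels.values():
            profile = "undetermined"
        else:
            profile = classify_profile(
                ClassLabel(labels["inhibition"]), ClassLabel(labels["atpase"]),
                ClassLabel(labels["efflux"])).value
        results.append(ScreenResult(cid, labels, profile, votes))
    return results


# ---------------------------------------------------------------------------
# top-level experiment pipeline


def default_candidate_configs(n_descriptors: int, n_seeds: int = 20,
                              k_values: Sequence[int] | None = None,
                              ) -> list[TreeConfig]:
    """Candidate grid: random trees over seeds × K, plus C4.5 leaf sizes."""
    if k_values is None:
        k_values = sorted({2, max(2, n_descriptors // 2), n_descriptors})
    k_values = [k for k in k_values if 1 <= k <= n_descriptors]
    configs = [TreeConfig(algorithm="random_tree", k_attributes=k, seed=s)
               for s in range(1, n_seeds + 1) for k in k_values]
    configs += [TreeConfig(algorithm="c45", min_instances=m) for m in range(1, 6)]
    return configs


@dataclass
class ExperimentResult:
    """Everything one endpoint's modelling run produces."""

    endpoint: str
    selected_descriptors: list[str]
    split: "object"
    candidate_reports: list[ValidationReport]
    consensus: ConsensusModel
    consensus_loo: ValidationReport
    test_report: ValidationReport
    test_predictions: list[ScoredPrediction]


def run_experiment(data: LabeledDataset, endpoint: str,
                   test_per_class: int = 10,
                   selection_config=None,
                   candidate_configs: Sequence[TreeConfig] | None = None,
                   n_seeds: int = 20,
                   gate: SelectionGate = DEFAULT_GATE,
                   standardize: bool = True) -> ExperimentResult:
    """Full single-endpoint pipeline on a labelled descriptor dataset.

    Steps: constant and inter-correlation pruning → sphere-exclusion
    train/test split → GA/CFS descriptor-subset selection on the training
    set → candidate tree training with LOO-CV gating → AD-aware consensus →
    consensus evaluation on the held-out test set.
    """
    from .preprocess import (FeatureSelectionConfig, PreprocessConfig,
                             correlation_filter, ga_subset_search,
                             remove_constant)
    from .splitting import SplitConfig, sphere_exclusion_split

    pruned = correlation_filter(remove_constant(data.table), PreprocessConfig())
    pruned_data = LabeledDataset(pruned, data.labels, dict(data.meta))
    split = sphere_exclusion_split(
        pruned_data, endpoint,
        SplitConfig(test_per_class=test_per_class, standardize=standardize))
    training = pruned_data.subset(split.training_ids)
    test = pruned_data.subset(split.test_ids)

    selection_config = selection_config or FeatureSelectionConfig()
    selected, _freq = ga_subset_search(training, endpoint, selection_config)
    training = LabeledDataset(training.table.select(selected), training.labels)
    test = LabeledDataset(test.table.select(selected), test.labels)

    if candidate_configs is None:
        candidate_configs = default_candidate_configs(len(selected), n_seeds)
    reports, passing, member_preds = [], [], []
    for config in candidate_configs:
        report, preds = loo_cv(training, endpoint, config)
        reports.append(report)
        if passes_selection_gate(report, gate):
            passing.append((config, preds))
    if not passing:
        raise ValueError(f"no candidate model passed the gate for {endpoint!r}")
    y_train = training.label_vector(endpoint)
    members, member_reports = [], []
    for config, preds in passing:
        est = _estimator_for(config).fit(training.table.data, y_train)
        est.tree_.training_ids = training.table.compound_ids
        members.append((est.tree_, fit_ad(training.table, standardize=standardize)))
        member_preds.append(preds)
    consensus = ConsensusModel(members, endpoint,
                               member_reports=[r for r in reports
                                               if passes_selection_gate(r, gate)])
    consensus_loo = consensus_loo_report(training, endpoint, consensus, member_preds)

    test_preds, flags = [], []
    for cid in test.table.compound_ids:
        pred = consensus_predict(consensus, test.table.row(cid))
        if pred.label == "out_of_domain":
            flags.append(f"{cid}: out of domain on the test set; voted by all")
            pred = consensus_predict(consensus, test.table.row(cid),
                                     mode="zero_to_max")
        label = pred.label if pred.label != "out_of_domain" else "N"
        prob = pred.mean_y_probability if pred.mean_y_probability is not None else 0.5
        test_preds.append(ScoredPrediction(cid, test.label(endpoint, cid).value,
                                           label, prob))
    test_report = report_from_predictions(
        test_preds, model_name=f"consensus[{endpoint}] test", flags=flags)
    return ExperimentResult(
        endpoint=endpoint,
        selected_descriptors=list(selected),
        split=split,
        candidate_reports=reports,
        consensus=consensus,
        consensus_loo=consensus_loo,
        test_report=test_report,
        test_predictions=test_preds,
    )
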