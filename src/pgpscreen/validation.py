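"""Classifier validation: confusion-matrix statistics and leave-one-out CV.

Class Y is the positive class throughout.  Sensitivity and specificity are
reported as percentages of the Y and N class sizes (the per-class "TP" and
"TN" rates of the result tables), accuracy as a percentage of all compounds.
The dimensionless statistics are the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

Cohen's kappa (chance-corrected agreement) and the rank-based ROC AUC.  A
model qualifies for the consensus layer only when its LOO-CV statistics meet
the selection gate: accuracy ≥ 70%, MCC ≥ 0.40, kappa ≥ 0.40, AUC ≥ 0.60.
The No-model baseline assigns every compound to the most represented class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import ClassLabel, LabeledDataset
from .trees import DecisionTree, TreeConfig, _estimator_for

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with Y as the positive class.

    FP counts class-N compounds predicted Y; FN counts class-Y compounds
    predicted N.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must count at least one prediction")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        """True-positive rate, percent of the Y class."""
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        """True-negative rate, percent of the N class."""
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


@dataclass(frozen=True)
class ScoredPrediction:
    """One compound's truth, predicted label and leaf Y-probability."""

    compound_id: str
    true: str
    pred: str
    y_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.y_probability <= 1.0:
            raise ValueError("y_probability must lie in [0, 1]")


@dataclass
class ValidationReport:
    """Summary statistics of one validation run (percent / dimensionless)."""

    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    kappa: float
    auc: float
    no_model_accuracy: float
    model_name: str = ""
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "confusion": self.confusion.to_dict(),
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
            "accuracy": round(self.accuracy, 1),
            "mcc": round(self.mcc, 2),
            "kappa": round(self.kappa, 2),
            "auc": round(self.auc, 2),
            "no_model_accuracy": round(self.no_model_accuracy, 1),
            "flags": list(self.flags),
        }


def confusion(predictions: Sequence[ScoredPrediction]) -> ConfusionMatrix:
    """Tally a confusion matrix from scored predictions (Y positive)."""
    if not predictions:
        raise ValueError("no predictions to tally")
    tp = sum(1 for p in predictions if p.true == "Y" and p.pred == "Y")
    fn = sum(1 for p in predictions if p.true == "Y" and p.pred == "N")
    tn = sum(1 for p in predictions if p.true == "N" and p.pred == "N")
    fp = sum(1 for p in predictions if p.true == "N" and p.pred == "Y")
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when a marginal is empty."""
    denom = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
             * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if denom == 0:
        logger.warning("MCC denominator has a zero factor; returning 0 by convention")
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa, the chance-corrected proportional agreement."""
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
          + (cm.tn + cm.fn) * (cm.tn + cm.fp)) / (n * n)
    if pe == 1.0:
        logger.warning("kappa undefined (chance agreement = 1); returning 0")
        return 0.0
    return (po - pe) / (1.0 - pe)


def roc_auc(predictions: Sequence[ScoredPrediction]) -> float:
    """Rank-based AUC: P(random Y outscores random N), ties counted half.

    Equals the trapezoidal area under the ROC step curve.
    """
    scores_y = np.array([p.y_probability for p in predictions if p.true == "Y"])
    scores_n = np.array([p.y_probability for p in predictions if p.true == "N"])
    if len(scores_y) == 0 or len(scores_n) == 0:
        raise ValueError("ROC AUC requires both classes among the predictions")
    diff = scores_y[:, None] - scores_n[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (len(scores_y) * len(scores_n)))


def no_model_baseline(labels: Sequence[ClassLabel | str]) -> float:
    """Accuracy (%) of assigning every compound to the majority class."""
    if not labels:
        raise ValueError("no labels")
    values = [lab.value if isinstance(lab, ClassLabel) else str(lab) for lab in labels]
    n_y = values.count("Y")
    n_n = len(values) - n_y
    if n_y == n_n:
        return 50.0
    return 100.0 * max(n_y, n_n) / len(values)


@dataclass(frozen=True)
class SelectionGate:
    """Minimum LOO-CV statistics a model must reach to enter a consensus."""

    min_accuracy: float = 70.0
    min_mcc: float = 0.40
    min_kappa: float = 0.40
    min_auc: float = 0.60


DEFAULT_GATE = SelectionGate()


def passes_selection_gate(report: ValidationReport,
                          gate: SelectionGate = DEFAULT_GATE) -> bool:
    """True iff accuracy, MCC, kappa and AUC all meet the gate (inclusive)."""
    return (report.accuracy >= gate.min_accuracy
            and report.mcc >= gate.min_mcc
            and report.kappa >= gate.min_kappa
            and report.auc >= gate.min_auc)


def report_from_predictions(predictions: Sequence[ScoredPrediction],
                            model_name: str = "",
                            flags: Sequence[str] = ()) -> ValidationReport:
    cm = confusion(predictions)
    return ValidationReport(
        confusion=cm,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        mcc=mcc(cm),
        kappa=kappa(cm),
        auc=roc_auc(predictions),
        no_model_accuracy=no_model_baseline([p.true for p in predictions]),
        model_name=model_name,
        flags=list(flags),
    )


def loo_cv(data: LabeledDataset, endpoint: str,
           config: TreeConfig) -> tuple[ValidationReport, list[ScoredPrediction]]:
    """Leave-one-out cross-validation of one tree configuration.

    Each compound is predicted by a tree trained on the other n−1 compounds
    with the identical configuration (same seed for a random tree, matching
    the one-model-per-(S, K) reading of the model names).  Statistics are
    pooled over the n held-out predictions; the AUC uses the pooled leaf
    probabilities.
    """
    ids = data.table.compound_ids
    n = len(ids)
    if n < 3:
        raise ValueError("LOO-CV needs at least 3 compounds")
    y_all = data.label_vector(endpoint)
    if len(set(y_all)) < 2:
        raise ValueError("LOO-CV needs both classes present")
    X = data.table.data
    predictions: list[ScoredPrediction] = []
    flags: list[str] = []
    for i, cid in enumerate(ids):
        mask = np.arange(n) != i
        y_train = y_all[mask]
        if len(set(y_train)) < 2:
            flags.append(f"fold {cid}: single-class training fold")
            logger.warning("LOO fold for %s lost one class entirely", cid)
        est = _estimator_for(config).fit(X.iloc[mask], y_train)
        pred = est.tree_.predict_row(X.iloc[i])
        predictions.append(ScoredPrediction(cid, y_all[i], pred.label,
                                            pred.y_probability))
    cm = confusion(predictions)
    report = ValidationReport(
        confusion=cm,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        mcc=mcc(cm),
        kappa=kappa(cm),
        auc=roc_auc(predictions),
        no_model_accuracy=no_model_baseline(list(y_all)),
        model_name=config.name,
        flags=flags,
    )
    return report, predictions
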