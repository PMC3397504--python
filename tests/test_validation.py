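"""Confusion-matrix statistics, LOO-CV and the model-selection gate."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score

import pgpscreen as pg
from pgpscreen import (ConfusionMatrix, ScoredPrediction, confusion, kappa,
                       loo_cv, mcc, no_model_baseline, passes_selection_gate,
                       roc_auc)
from pgpscreen.validation import SelectionGate, ValidationReport

from conftest import make_dataset


def _vectors(cm):
    """Reconstruct truth/prediction 0/1 vectors from a confusion matrix."""
    truth = [1] * (cm.tp + cm.fn) + [0] * (cm.tn + cm.fp)
    pred = [1] * cm.tp + [0] * cm.fn + [0] * cm.tn + [1] * cm.fp
    return np.array(truth), np.array(pred)


class TestConfusion:
    def test_all_correct(self):
        preds = [ScoredPrediction(f"c{i}", t, t, 0.5)
                 for i, t in enumerate("YYYNN")]
        cm = confusion(preds)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (3, 0, 2, 0)

    def test_all_inverted(self):
        preds = [ScoredPrediction(f"c{i}", t, "N" if t == "Y" else "Y", 0.5)
                 for i, t in enumerate("YYNN")]
        cm = confusion(preds)
        assert cm.tp == 0 and cm.tn == 0 and cm.fn == 2 and cm.fp == 2

    def test_rates_reconstructed_from_class_sizes(self):
        # 16 Y / 23 N with rates 68.8 / 82.6 corresponds to counts 11/5/19/4
        cm = ConfusionMatrix(tp=11, fn=5, tn=19, fp=4)
        assert round(cm.sensitivity, 1) == 68.8
        assert round(cm.specificity, 1) == 82.6
        assert round(cm.accuracy, 1) == 76.9


class TestMcc:
    @pytest.mark.parametrize("counts, expected", [
        ((11, 5, 19, 4), 0.52),
        ((20, 4, 10, 5), 0.51),
        ((16, 3, 16, 4), 0.64),
    ])
    def test_worked_examples(self, counts, expected):
        assert round(mcc(ConfusionMatrix(*counts)), 2) == expected

    def test_perfect_prediction(self):
        assert mcc(ConfusionMatrix(tp=5, fn=0, tn=5, fp=0)) == 1.0

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionMatrix(tp=5, fn=0, tn=0, fp=0)) == 0.0

    def test_matches_phi_exhaustively(self):
        """MCC equals the Pearson phi of reconstructed vectors, total <= 20."""
        for total in range(2, 21):
            for tp, fn, tn in itertools.product(range(total + 1), repeat=3):
                fp = total - tp - fn - tn
                if fp < 0:
                    continue
                cm = ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)
                truth, pred = _vectors(cm)
                ours = mcc(cm)
                if truth.std() == 0 or pred.std() == 0:
                    assert ours == 0.0
                else:
                    phi = np.corrcoef(truth, pred)[0, 1]
                    assert ours == pytest.approx(phi, abs=1e-12)


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa(ConfusionMatrix(tp=4, fn=0, tn=6, fp=0)) == 1.0

    def test_worked_example(self):
        assert round(kappa(ConfusionMatrix(tp=16, fn=3, tn=16, fp=4)), 2) == 0.64

    def test_chance_level_agreement(self):
        # prediction independent of truth with matching marginals
        cm = ConfusionMatrix(tp=4, fn=4, tn=4, fp=4)
        assert kappa(cm) == pytest.approx(0.0)

    def test_equals_mcc_for_symmetric_matrices(self):
        for tp, fp in itertools.product(range(1, 8), range(0, 8)):
            cm = ConfusionMatrix(tp=tp, fn=fp, tn=tp, fp=fp)
            assert kappa(cm) == pytest.approx(mcc(cm), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                     st.integers(0, 30), st.integers(0, 30)).filter(
                         lambda t: sum(t) > 0))
    def test_matches_sklearn_and_bounds(self, counts):
        cm = ConfusionMatrix(*counts)
        truth, pred = _vectors(cm)
        assert -1.0 <= kappa(cm) <= 1.0
        assert -1.0 <= mcc(cm) <= 1.0
        if truth.std() > 0 and pred.std() > 0:
            assert kappa(cm) == pytest.approx(cohen_kappa_score(truth, pred))
            assert mcc(cm) == pytest.approx(matthews_corrcoef(truth, pred))


class TestRocAuc:
    def test_perfect_separation(self):
        preds = [ScoredPrediction("a", "Y", "Y", 0.9),
                 ScoredPrediction("b", "Y", "Y", 0.8),
                 ScoredPrediction("c", "N", "N", 0.2)]
        assert roc_auc(preds) == 1.0

    def test_all_ties(self):
        preds = [ScoredPrediction(f"c{i}", t, t, 0.5)
                 for i, t in enumerate("YYNN")]
        assert roc_auc(preds) == 0.5

    def test_pairwise_example(self):
        # 4 Y-N pairs, 3 wins: 0.9>0.6, 0.9>0.1, 0.4<0.6, 0.4>0.1
        preds = [ScoredPrediction("a", "Y", "Y", 0.9),
                 ScoredPrediction("b", "Y", "N", 0.4),
                 ScoredPrediction("c", "N", "Y", 0.6),
                 ScoredPrediction("d", "N", "N", 0.1)]
        assert roc_auc(preds) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([ScoredPrediction("a", "Y", "Y", 0.9)])

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("YN"),
                              st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0])),
                    min_size=2, max_size=12).filter(
                        lambda l: len({t for t, _ in l}) == 2))
    def test_matches_pairwise_oracle(self, items):
        preds = [ScoredPrediction(f"c{i}", t, t, p)
                 for i, (t, p) in enumerate(items)]
        wins = trials = 0
        for py in (p.y_probability for p in preds if p.true == "Y"):
            for pn in (p.y_probability for p in preds if p.true == "N"):
                trials += 1
                wins += 1 if py > pn else 0.5 if py == pn else 0
        assert roc_auc(preds) == pytest.approx(wins / trials)
        truth = [1 if p.true == "Y" else 0 for p in preds]
        scores = [p.y_probability for p in preds]
        assert roc_auc(preds) == pytest.approx(roc_auc_score(truth, scores))


class TestNoModel:
    @pytest.mark.parametrize("n_y, n_n, expected", [
        (16, 23, 59.0), (5, 0, 100.0), (4, 4, 50.0),
    ])
    def test_baseline(self, n_y, n_n, expected):
        labels = [pg.ClassLabel("Y")] * n_y + [pg.ClassLabel("N")] * n_n
        assert round(no_model_baseline(labels), 1) == expected


def _report(acc, m, k, auc):
    cm = ConfusionMatrix(tp=1, fn=1, tn=1, fp=1)
    return ValidationReport(confusion=cm, sensitivity=0, specificity=0,
                            accuracy=acc, mcc=m, kappa=k, auc=auc,
                            no_model_accuracy=50.0)


class TestSelectionGate:
    @pytest.mark.parametrize("stats, ok", [
        ((76.9, 0.52, 0.52, 0.76), True),
        ((53.8, 0.19, 0.48, 0.52), False),
        ((70.0, 0.40, 0.40, 0.60), True),   # inclusive boundary
        ((69.9, 0.52, 0.52, 0.76), False),
        ((76.9, 0.39, 0.52, 0.76), False),
    ])
    def test_gate(self, stats, ok):
        assert passes_selection_gate(_report(*stats)) is ok


class TestLooCv:
    def test_trivially_separable_three_compounds(self):
        # Each fold trains on 2 compounds split cleanly by D1; enumerate:
        # held-out c1 -> left leaf (pure N? depends) ... all predicted right.
        data = make_dataset([[0.0], [0.1], [5.0], [5.1]], [0, 0, 1, 1])
        report, preds = loo_cv(data, "inhibition",
                               pg.TreeConfig(k_attributes=1, seed=1))
        assert report.accuracy == 100.0
        assert len(preds) == 4

    def test_deterministic(self, small_noiseless):
        config = pg.TreeConfig(k_attributes=5, seed=3)
        r1, p1 = loo_cv(small_noiseless, "inhibition", config)
        r2, p2 = loo_cv(small_noiseless, "inhibition", config)
        assert p1 == p2
        assert r1.to_dict() == r2.to_dict()

    def test_majority_classifier_equals_no_model(self):
        # C4.5 with min_instances = n collapses to the majority class
        data = make_dataset([[i] for i in range(8)] , [1, 0, 0, 0, 1, 0, 0, 0])
        config = pg.TreeConfig(algorithm="c45", min_instances=7)
        report, _ = loo_cv(data, "inhibition", config)
        assert report.accuracy == pytest.approx(report.no_model_accuracy)

    def test_needs_both_classes(self):
        data = make_dataset([[1.0], [2.0], [3.0]], [1, 1, 1])
        with pytest.raises(ValueError):
            loo_cv(data, "inhibition", pg.TreeConfig(k_attributes=1))
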