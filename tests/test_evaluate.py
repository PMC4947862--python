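"""ROC/AUC machinery, MCC operating points, and the paired bootstrap test."""

import numpy as np
import pandas as pd
import pytest

from sappred.evaluate import (
    ConfusionCounts, auc, best_mcc_cutoff, bootstrap_auc_test, confusion_at,
    evaluation_report, mcc, metrics_at_cutoff, precision_recall_curve,
    roc_curve, sensitivity_at_specificity,
)

from oracles import exhaustive_best_mcc, pairwise_auc


def _tied_instance(rng, n=60):
    scores = np.round(rng.standard_normal(n), 1)   # rounding forces ties
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


def test_auc_known_values():
    assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert auc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0
    assert auc([1, 1, 1, 1], [0, 0, 1, 1]) == 0.5
    assert auc([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)


def test_auc_matches_pair_counting_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(20):
        scores, labels = _tied_instance(rng)
        assert auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12)


def test_auc_rejects_single_class_and_nonfinite():
    with pytest.raises(ValueError, match="both classes"):
        auc([1, 2], [1, 1])
    with pytest.raises(ValueError, match="finite"):
        auc([1, np.nan], [0, 1])
    with pytest.raises(ValueError, match="align"):
        auc([1, 2, 3], [0, 1])


def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(1)
    scores, labels = _tied_instance(rng)
    curve = roc_curve(scores, labels)
    assert curve.iloc[0]["sensitivity"] == 0.0
    assert curve.iloc[0]["specificity"] == 1.0
    assert curve.iloc[-1]["sensitivity"] == 1.0
    assert curve["sensitivity"].is_monotonic_increasing
    assert curve["specificity"].is_monotonic_decreasing


def test_mcc_hand_cases():
    assert mcc(ConfusionCounts(tp=5, fp=0, fn=0, tn=5)) == 1.0
    assert mcc(ConfusionCounts(tp=0, fp=5, fn=5, tn=0)) == -1.0
    assert mcc(ConfusionCounts(tp=5, fp=5, fn=0, tn=0)) == 0.0  # degenerate
    # tp=4 fp=1 fn=1 tn=4: (16-1)/sqrt(5*5*5*5) = 0.6
    assert mcc(ConfusionCounts(tp=4, fp=1, fn=1, tn=4)) == pytest.approx(0.6)


def test_confusion_at_rule_is_score_ge_cutoff():
    c = confusion_at([0.2, 0.5, 0.5, 0.9], [0, 0, 1, 1], 0.5)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 0, 1)


def test_best_mcc_cutoff_matches_exhaustive_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        scores, labels = _tied_instance(rng)
        cut, best = best_mcc_cutoff(scores, labels)
        assert best == pytest.approx(exhaustive_best_mcc(scores, labels), abs=1e-12)
        assert mcc(confusion_at(scores, labels, cut)) == pytest.approx(best)


def test_best_mcc_cutoff_tie_goes_to_smallest():
    # perfectly separable: any cutoff in the gap attains MCC 1; the first
    # candidate attaining the maximum is the midpoint of the widest-left gap
    cut, best = best_mcc_cutoff([0.0, 0.1, 0.8, 0.9], [0, 0, 1, 1])
    assert best == 1.0
    assert cut == pytest.approx(0.45)


def test_metrics_at_cutoff_reports_nan_on_empty_cells():
    m = metrics_at_cutoff([0.1, 0.2], [0, 1], cutoff=10.0)  # nothing predicted +
    assert np.isnan(m["ppv"])
    assert m["specificity"] == 1.0 and m["sensitivity"] == 0.0


def test_sensitivity_at_specificity_step_convention():
    scores = [0.1, 0.2, 0.3, 0.4, 0.35, 0.45]
    labels = [0, 0, 0, 0, 1, 1]
    # spec 0.75 is achievable exactly (threshold 0.35 -> fp=1); sens there = 1
    assert sensitivity_at_specificity(scores, labels, 0.75) == 1.0
    # an unreachable target falls back to the smallest specificity >= target
    assert sensitivity_at_specificity(scores, labels, 0.9) == pytest.approx(0.5)


def test_precision_recall_curve_ends():
    curve = precision_recall_curve([0.1, 0.4, 0.6, 0.9], [0, 1, 0, 1])
    assert np.isnan(curve.iloc[0]["precision"])   # nothing predicted positive
    assert curve.iloc[-1]["recall"] == 1.0
    assert curve.iloc[-1]["precision"] == pytest.approx(0.5)


def test_bootstrap_test_on_identical_scores_is_null():
    rng = np.random.default_rng(3)
    s = rng.standard_normal(100)
    y = rng.integers(0, 2, 100)
    y[0], y[1] = 0, 1
    delta, p = bootstrap_auc_test(s, s.copy(), y, n_boot=200, seed=0)
    assert delta == 0.0
    assert p == 1.0


def test_bootstrap_test_detects_clear_difference():
    rng = np.random.default_rng(4)
    n = 300
    y = np.repeat([0, 1], n // 2)
    strong = 2.0 * y + rng.standard_normal(n)
    weak = rng.standard_normal(n)
    delta, p = bootstrap_auc_test(strong, weak, y, n_boot=300, seed=0)
    assert delta > 0.3
    assert p < 1e-6


def test_bootstrap_test_requires_paired_design():
    with pytest.raises(ValueError, match="paired"):
        bootstrap_auc_test([1, 2, 3], [1, 2], [0, 1, 1])


def test_evaluation_report_orders_by_auc():
    rng = np.random.default_rng(5)
    n = 400
    y = np.repeat([0, 1], n // 2)
    scored = {
        "weak": (0.5 * y + rng.standard_normal(n), y),
        "strong": (2.5 * y + rng.standard_normal(n), y),
        "medium": (1.2 * y + rng.standard_normal(n), y),
    }
    report = evaluation_report(scored, n_boot=200, seed=1)
    assert list(report["classifier"]) == ["strong", "medium", "weak"]
    assert report["auc"].is_monotonic_decreasing
    assert np.isnan(report["p_vs_next"].iloc[-1])
    assert report.loc[0, "p_vs_next"] < 0.05
    assert bool(report.loc[0, "significant_vs_next"])


def test_evaluation_report_honours_fixed_cutoffs():
    y = np.array([0, 0, 1, 1])
    s = np.array([0.1, 0.2, 0.8, 0.9])
    rep = evaluation_report({"m": (s, y), "m2": (s, y)},
                            cutoffs={"m": 0.85}, n_boot=50, seed=0)
    row = rep.set_index("classifier").loc["m"]
    assert row["cutoff"] == 0.85
    assert row["sensitivity"] == 0.5


def test_evaluation_report_rejects_mismatched_labels():
    with pytest.raises(ValueError, match="same labeled"):
        evaluation_report({"a": (np.array([1.0, 2.0]), np.array([0, 1])),
                           "b": (np.array([1.0, 2.0]), np.array([1, 0]))})
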