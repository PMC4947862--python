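"""Classifier fitting, feature ranking, and cross-validated forward selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sappred.evaluate import auc
from sappred.selection import (
    PFS1, PFS2, PFS3, SelectionTrace, _fit_logit, _ridge_logit, choose_prefix,
    fit_decision_tree, fit_logistic_pfs, forward_selection,
    rank_features_forest, rank_features_logistic,
)
from sappred.simulate import planted_matrix


def test_pfs_compositions():
    assert PFS1 == ("GO.BP", "evolutionary.rate", "disordered.region")
    assert PFS2 == ("GO.BP", "PROVEAN", "SIFT", "GERP", "disordered.region")
    assert PFS3 == ("PON-P2", "GO.BP", "PROVEAN")


def test_decision_tree_on_separable_feature():
    m = planted_matrix(400, 20, effects=[6.0], n_noise=1, seed=0)
    clf, summary = fit_decision_tree(m, ["inf1", "noise1"], seed=0)
    assert summary.loc[0, "feature"] == "inf1"       # root splits on signal
    assert summary.loc[0, "coverage"] == pytest.approx(1.0)
    leaves = summary[summary["is_leaf"]]
    assert (leaves["frac_benign"] + leaves["frac_pathogenic"]).round(9).eq(1.0).all()
    p = clf.predict_proba(m.set_index("sap_key"))
    assert auc(p.to_numpy(), (m["label"] == "pathogenic").astype(int).to_numpy()) > 0.99


def test_decision_tree_requires_both_classes():
    m = planted_matrix(100, 10, effects=[1.0], n_noise=0, seed=0)
    with pytest.raises(ValueError, match="both classes"):
        fit_decision_tree(m[m["label"] == "benign"], ["inf1"])


def test_ridge_logit_handles_perfect_separation():
    x = np.linspace(-2, 2, 40).reshape(-1, 1)
    y = (x.ravel() > 0).astype(int)
    fit = _fit_logit(x, y)
    assert fit.ridge_fallback
    assert np.all(np.isfinite(fit.params)) and np.all(np.isfinite(fit.bse))
    p = fit.predict(x)
    assert p[0] < 0.5 < p[-1]


def test_logit_fit_recovers_known_coefficients():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((4000, 1))
    eta = -0.5 + 1.5 * x.ravel()
    y = (rng.random(4000) < 1 / (1 + np.exp(-eta))).astype(int)
    fit = _fit_logit(x, y)
    assert not fit.ridge_fallback
    assert fit.params[0] == pytest.approx(-0.5, abs=0.15)
    assert fit.params[1] == pytest.approx(1.5, abs=0.2)
    assert fit.pvalues[1] < 1e-10


def test_logistic_ranking_puts_signal_first():
    m = planted_matrix(800, 40, effects=[1.5], n_noise=4, seed=1)
    ranked = rank_features_logistic(m, ["noise1", "inf1", "noise2", "noise3", "noise4"])
    assert ranked[0] == "inf1"


def test_forest_ranking_puts_signal_first():
    m = planted_matrix(800, 40, effects=[1.5], n_noise=4, seed=2)
    ranked = rank_features_forest(
        m, ["noise1", "inf1", "noise2", "noise3", "noise4"],
        seed=0, n_estimators=50)
    assert ranked[0] == "inf1"


def test_ridge_fallback_preserves_ranking_under_separation():
    m = planted_matrix(300, 20, effects=[50.0], n_noise=3, seed=3)
    ranked = rank_features_logistic(m, ["noise1", "inf1", "noise2", "noise3"])
    assert ranked[0] == "inf1"


def _trace(means, sds, features, n_eval=100):
    steps = pd.DataFrame({
        "step": np.arange(1, len(means) + 1),
        "mean_train_error": means, "sd_train_error": sds,
        "mean_test_error": means, "sd_test_error": sds,
        "feature": features,
        "selection_frequency": 1.0,
    })
    return SelectionTrace(ranker="logistic", iterations=n_eval // 5, folds=5,
                          seed=0, steps=steps)


def test_choose_prefix_one_se_rule_prefers_smaller_model():
    # minimum at step 3, but step 2 is within one SE of it
    t = _trace([0.30, 0.201, 0.20], [0.05, 0.05, 0.05], ["f1", "f2", "f3"])
    assert choose_prefix(t) == ("f1", "f2")


def test_choose_prefix_takes_minimum_when_gap_is_large():
    t = _trace([0.30, 0.25, 0.10], [0.001, 0.001, 0.001], ["f1", "f2", "f3"])
    assert choose_prefix(t) == ("f1", "f2", "f3")


def test_choose_prefix_empty_trace():
    with pytest.raises(ValueError, match="empty"):
        choose_prefix(_trace([], [], []))


def test_forward_selection_trace_shapes_and_determinism():
    m = planted_matrix(400, 40, effects=[1.5, 1.0], n_noise=3, seed=4)
    feats = ["inf1", "inf2", "noise1", "noise2", "noise3"]
    a = forward_selection(m, feats, ranker="logistic", k=4, iterations=2, seed=7)
    b = forward_selection(m, feats, ranker="logistic", k=4, iterations=2, seed=7)
    pd.testing.assert_frame_equal(a.steps, b.steps)
    assert len(a.steps) == 5
    # each (iteration, fold) ranking places exactly one feature per step
    assert np.allclose(a.step_frequency.sum(axis=0), 1.0)
    assert np.allclose(a.first_k_frequency["first5"], 1.0)
    assert a.steps["feature"].iloc[0] == "inf1"


def test_forward_selection_respects_max_steps():
    m = planted_matrix(300, 30, effects=[1.5], n_noise=4, seed=5)
    t = forward_selection(m, ["inf1", "noise1", "noise2", "noise3", "noise4"],
                          ranker="logistic", k=3, iterations=1, seed=0,
                          max_steps=2)
    assert len(t.steps) == 2


def test_forward_selection_rejects_unknown_ranker():
    m = planted_matrix(100, 20, effects=[1.0], n_noise=1, seed=6)
    with pytest.raises(ValueError, match="unknown ranker"):
        forward_selection(m, ["inf1", "noise1"], ranker="boosting")


def test_fitted_pfs_auc_matches_gaussian_theory():
    # single feature, class separation d: theoretical AUC = Phi(d / sqrt(2))
    d = 1.0
    m_train = planted_matrix(4000, 100, effects=[d], n_noise=0, seed=8)
    m_test = planted_matrix(4000, 100, effects=[d], n_noise=0, seed=9)
    clf = fit_logistic_pfs(m_train.set_index("sap_key"), ("inf1",))
    scores = clf.predict_proba(m_test.set_index("sap_key")).to_numpy()
    y = (m_test["label"] == "pathogenic").astype(int).to_numpy()
    assert auc(scores, y) == pytest.approx(norm.cdf(d / np.sqrt(2)), abs=0.03)


def test_fitted_pfs_is_uninformative_on_permuted_labels():
    rng = np.random.default_rng(10)
    m = planted_matrix(2000, 100, effects=[1.5], n_noise=0, seed=10)
    m["label"] = rng.permutation(m["label"].to_numpy())
    half = len(m) // 2
    clf = fit_logistic_pfs(m.iloc[:half].set_index("sap_key"), ("inf1",))
    scores = clf.predict_proba(m.iloc[half:].set_index("sap_key")).to_numpy()
    y = (m.iloc[half:]["label"] == "pathogenic").astype(int).to_numpy()
    assert auc(scores, y) == pytest.approx(0.5, abs=0.05)
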