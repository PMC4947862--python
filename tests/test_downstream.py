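"""Difficult-SAP analysis and the annotation-growth bias comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sappred.downstream import (
    BiasGroups, MethodPredictions, assign_bias_groups, bias_analysis,
    difficult_saps, false_sets, gene_fn_excess, one_sided_t_test,
    rescue_fractions,
)
from sappred.ontology import AnnotationCorpus
from sappred.simulate import (
    SimulationConfig, simulate_annotations, simulate_ontology,
    simulate_two_releases,
)


def _methods():
    keys = [f"S{i}" for i in range(6)]
    truth = ["benign", "benign", "benign", "pathogenic", "pathogenic", "pathogenic"]
    # per-method predicted labels
    preds = {
        "A": ["pathogenic", "pathogenic", "benign", "benign", "benign", "pathogenic"],
        "B": ["pathogenic", "benign", "benign", "benign", "pathogenic", "pathogenic"],
    }
    return [MethodPredictions(m, pd.Series(p, index=keys),
                              pd.Series(truth, index=keys))
            for m, p in preds.items()]


def test_false_sets_and_difficult_intersection():
    sets = false_sets(_methods())
    assert sets["A"] == ({"S0", "S1"}, {"S3", "S4"})
    assert sets["B"] == ({"S0"}, {"S3"})
    diff_fp, diff_fn, venn_fp, venn_fn = difficult_saps(sets)
    assert diff_fp == {"S0"}
    assert diff_fn == {"S3"}
    # Venn regions partition each union
    assert venn_fp == {frozenset({"A", "B"}): 1, frozenset({"A"}): 1}
    assert venn_fn == {frozenset({"A", "B"}): 1, frozenset({"A"}): 1}
    assert sum(venn_fp.values()) == len({"S0", "S1"})


def test_false_sets_rejects_disagreeing_truth():
    a, b = _methods()
    b.truth["S0"] = "pathogenic"
    with pytest.raises(ValueError, match="true labels"):
        false_sets([a, b])


def test_false_sets_rejects_different_universe():
    a, b = _methods()
    b.predictions = b.predictions.iloc[:-1]
    with pytest.raises(ValueError, match="universe"):
        false_sets([a, b])


def test_difficult_needs_two_methods():
    with pytest.raises(ValueError, match="at least 2"):
        difficult_saps({"A": (set(), set())})


def test_rescue_fractions_arithmetic():
    sets = false_sets(_methods())
    r = rescue_fractions(sets).set_index("method")
    assert r.loc["A", "difficult_fp_share"] == pytest.approx(0.5)
    assert r.loc["A", "rescued_fp_share"] == pytest.approx(0.5)
    assert r.loc["B", "difficult_fn_share"] == pytest.approx(1.0)
    assert r.loc["B", "rescued_fn_share"] == pytest.approx(0.0)


def test_gene_fn_excess_flags_only_high_frequency_genes():
    difficult = {"G1:A1V", "G1:A2V", "G2:A1V", "G3:A1V", "G3:A2V"}
    gene_of = pd.Series({s: s.split(":")[0] for s in difficult})
    totals = pd.Series({"G1": 10, "G2": 50, "G3": 100})
    out = gene_fn_excess(difficult, totals, gene_of,
                         expected_rate=0.05, min_difficult=2)
    # G1: 2/10 = 0.2 > 0.05 -> flagged; G2: only 1 difficult SAP -> skipped;
    # G3: 2/100 = 0.02 <= 0.05 -> skipped
    assert list(out["gene_id"]) == ["G1"]
    assert out.loc[0, "fn_frequency"] == pytest.approx(0.2)


def test_gene_fn_excess_rate_bound_is_strict():
    difficult = {"G1:A1V", "G1:A2V"}
    gene_of = pd.Series({s: "G1" for s in difficult})
    out = gene_fn_excess(difficult, pd.Series({"G1": 40}), gene_of,
                         expected_rate=0.05)
    assert len(out) == 0          # 2/40 = 0.05 does not exceed the rate


def test_bias_groups_must_be_disjoint():
    with pytest.raises(ValueError, match="disjoint"):
        BiasGroups({"g1"}, {"g1"}, set())


def test_assign_bias_groups():
    years = {"g1": 2000, "g2": 2010, "g3": None}
    groups = assign_bias_groups(years, 2000, 2010, all_genes={"g1", "g2", "g3", "g4"})
    assert groups.group1 == {"g1"}
    assert groups.group2 == {"g2"}
    assert groups.group3 == {"g3", "g4"}


def test_one_sided_t_test_closed_form():
    t, df, p = one_sided_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(np.sqrt(1.5))     # 1 / sqrt(1 * 2/3)
    assert df == 4
    ref = stats.ttest_ind([2.0, 3.0, 4.0], [1.0, 2.0, 3.0],
                          equal_var=True, alternative="greater")
    assert p == pytest.approx(ref.pvalue)


def test_one_sided_t_test_guards():
    with pytest.raises(ValueError, match="n >= 2"):
        one_sided_t_test([1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="zero pooled variance"):
        one_sided_t_test([1.0, 1.0], [1.0, 1.0])


def _release_fixture(seed=0):
    # group sizes matter: ~75 vs ~150 genes give the t-test enough power for
    # a single-seed significance assertion at the default growth rates
    cfg = SimulationConfig(seed=seed, n_terms=120, depth=4,
                           n_disease_genes=150, n_neutral_genes=150)
    rng = np.random.default_rng(seed)
    dag = simulate_ontology(cfg, np.random.default_rng(rng.integers(2**31)))
    disease = [f"DG{i:04d}" for i in range(cfg.n_disease_genes)]
    neutral = [f"NG{i:04d}" for i in range(cfg.n_neutral_genes)]
    corpus = simulate_annotations(dag, disease, neutral, cfg,
                                  np.random.default_rng(rng.integers(2**31)))
    groups = {"group1": set(disease[:75]), "group2": set(disease[75:]),
              "group3": set(neutral)}
    old, new = simulate_two_releases(dag, corpus, groups, cfg,
                                     np.random.default_rng(rng.integers(2**31)))
    return dag, old, new, BiasGroups(**groups)


def test_bias_analysis_on_identical_releases_is_degenerate():
    dag, old, _, groups = _release_fixture()
    report = bias_analysis(old, old, dag, dag, groups)
    assert report["degenerate"].all()
    assert report["mean_a"].eq(0).all() and report["mean_b"].eq(0).all()


def test_bias_analysis_detects_planted_growth_difference():
    dag, old, new, groups = _release_fixture(seed=1)
    report = bias_analysis(old, new, dag, dag, groups).set_index("comparison")
    row = report.loc["group2>group3"]
    assert row["mean_a"] > row["mean_b"]
    assert row["p"] < 0.05


def test_bias_analysis_rejects_empty_group():
    dag, old, new, groups = _release_fixture()
    bad = BiasGroups(groups.group1, groups.group2, set())
    with pytest.raises(ValueError, match="group3 is empty"):
        bias_analysis(old, new, dag, dag, bad)


def test_corpus_copy_semantics_between_releases():
    dag, old, new, _ = _release_fixture()
    for g in old.genes():
        assert old.direct_annotations[g] <= new.direct_annotations.get(g, set())
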