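"""Ontology parsing, propagation, information content, and the GO.BP count."""

import math

import numpy as np
import pytest

from sappred.ontology import (
    BP, AnnotationCorpus, ICTable, OntologyDAG, OntologyError, OntologyTerm,
    ancestors, compute_ic, go_bp_count, go_bp_delta, parse_obo,
    propagate_annotations, write_obo,
)

from conftest import random_corpus
from oracles import brute_force_gobp, random_dag, reachable_ancestors


# ---------------------------------------------------------------------------
# DAG structure and OBO I/O
# ---------------------------------------------------------------------------

def test_dag_rejects_dangling_parent():
    with pytest.raises(OntologyError, match="missing parent"):
        OntologyDAG({"A": OntologyTerm("A", "a", BP, frozenset({"GHOST"}))})


def test_dag_rejects_cycle():
    with pytest.raises(OntologyError, match="cycle"):
        OntologyDAG({
            "A": OntologyTerm("A", "a", BP, frozenset({"B"})),
            "B": OntologyTerm("B", "b", BP, frozenset({"A"})),
        })


def test_dag_roots(diamond_dag):
    assert diamond_dag.roots == {"R"}


def test_obo_roundtrip_random_dags():
    rng = np.random.default_rng(7)
    for _ in range(20):
        dag = random_dag(rng, int(rng.integers(2, 40)))
        back = parse_obo(write_obo(dag))
        assert back.terms == dag.terms


def test_parse_obo_dangling_reference_is_an_error():
    text = (
        "format-version: 1.2\n\n[Term]\nid: T:1\nname: one\n"
        "namespace: biological_process\nis_a: T:MISSING\n"
    )
    with pytest.raises(OntologyError, match="T:MISSING"):
        parse_obo(text)


def test_parse_obo_skips_obsolete_terms():
    text = (
        "format-version: 1.2\n\n"
        "[Term]\nid: T:1\nname: one\nnamespace: biological_process\n\n"
        "[Term]\nid: T:2\nname: two\nnamespace: biological_process\n"
        "is_obsolete: true\n"
    )
    dag = parse_obo(text)
    assert "T:1" in dag and "T:2" not in dag


# ---------------------------------------------------------------------------
# Ancestors and propagation
# ---------------------------------------------------------------------------

def test_ancestors_chain(chain_dag):
    assert ancestors(chain_dag, "B") == {"A", "R"}
    assert ancestors(chain_dag, "R") == set()


def test_ancestors_diamond_no_duplicates(diamond_dag):
    assert ancestors(diamond_dag, "C") == {"A", "B", "R"}


def test_ancestors_unknown_term(chain_dag):
    with pytest.raises(OntologyError, match="unknown term"):
        ancestors(chain_dag, "NOPE")


def test_ancestors_matches_fixpoint_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        dag = random_dag(rng, int(rng.integers(3, 40)))
        for t in dag.terms:
            assert ancestors(dag, t) == reachable_ancestors(dag, t)


def test_propagation_true_path_rule(diamond_dag):
    c = AnnotationCorpus("t")
    c.add("g", "C", "IDA")
    closure = propagate_annotations(diamond_dag, c)
    assert closure["g"] == {"C", "A", "B", "R"}


def test_propagation_rejects_unknown_term(chain_dag):
    c = AnnotationCorpus("t")
    c.add("g", "NOPE")
    with pytest.raises(OntologyError, match="NOPE"):
        propagate_annotations(chain_dag, c)


def test_annotation_table_roundtrip(small_corpus):
    back = AnnotationCorpus.from_table(small_corpus.to_table())
    assert back.direct_annotations == small_corpus.direct_annotations


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

def test_ic_hand_computed(chain_dag):
    # closures: g1 -> {B,A,R}, g2 -> {A,R}, g3 -> {R}; N = 3
    c = AnnotationCorpus("t")
    c.add("g1", "B")
    c.add("g2", "A")
    c.add("g3", "R")
    ic = compute_ic(chain_dag, c, BP)
    assert ic.corpus_size == 3
    assert ic["R"] == pytest.approx(0.0)
    assert ic["A"] == pytest.approx(math.log(3 / 2))
    assert ic["B"] == pytest.approx(math.log(3))


def test_ic_root_is_exactly_zero_not_negative_zero(chain_dag):
    c = AnnotationCorpus("t")
    c.add("g1", "R")
    ic = compute_ic(chain_dag, c, BP)
    assert ic["R"] == 0.0 and math.copysign(1.0, ic["R"]) == 1.0


def test_ic_ignores_evidence_codes(chain_dag):
    a = AnnotationCorpus("a")
    b = AnnotationCorpus("b")
    for g, t in (("g1", "B"), ("g2", "A")):
        a.add(g, t, "IDA")
        b.add(g, t, "IEA")
    assert compute_ic(chain_dag, a, BP).ic == compute_ic(chain_dag, b, BP).ic


def test_ic_errors_when_namespace_unannotated(chain_dag):
    with pytest.raises(OntologyError, match="molecular_function"):
        c = AnnotationCorpus("t")
        c.add("g1", "B")
        compute_ic(chain_dag, c, "molecular_function")


# ---------------------------------------------------------------------------
# GO.BP multifunctionality
# ---------------------------------------------------------------------------

def _count_corpus(dag):
    """16 filler genes on the root; with g7/g8/g9 and a query gene gx the
    corpus has N = 20, so a two-gene term has ic = ln 10 ~ 2.30 (above the
    2.0 threshold) while a three-gene term has ic = ln(20/3) ~ 1.90 (below)."""
    c = AnnotationCorpus("t")
    for i in range(16):
        c.add(f"f{i}", "R")
    c.add("g7", "A")
    c.add("g8", "B")
    c.add("g9", "C")
    return c


@pytest.fixture
def count_dag():
    """R <- A <- B and R <- C."""
    return OntologyDAG({
        "R": OntologyTerm("R", "root", BP),
        "A": OntologyTerm("A", "a", BP, frozenset({"R"})),
        "B": OntologyTerm("B", "b", BP, frozenset({"A"})),
        "C": OntologyTerm("C", "c", BP, frozenset({"R"})),
    })


def test_gobp_ic_filter_applied_before_child_collapse(count_dag):
    # gene annotated to A, B, C with threshold 2.0: the IC filter first drops
    # A (ic ~ 1.61), so B no longer has a surviving ancestor -> count 2.
    # Collapsing before filtering would drop B under A and leave only C.
    corpus = _count_corpus(count_dag)
    corpus.add("gx", "A")
    corpus.add("gx", "B")
    corpus.add("gx", "C")
    ic = compute_ic(count_dag, corpus, BP)
    assert go_bp_count("gx", corpus, count_dag, ic, ic_threshold=2.0) == 2


def test_gobp_child_collapse_drops_descendants(count_dag):
    corpus = _count_corpus(count_dag)
    corpus.add("gx", "A")
    corpus.add("gx", "B")
    ic = compute_ic(count_dag, corpus, BP)
    # with threshold 0 both survive the IC filter; B collapses under A
    assert go_bp_count("gx", corpus, count_dag, ic, ic_threshold=0.0) == 1


def test_gobp_threshold_boundary_is_kept(count_dag):
    corpus = _count_corpus(count_dag)
    corpus.add("gx", "B")
    ic = compute_ic(count_dag, corpus, BP)
    exactly = ic["B"]
    assert go_bp_count("gx", corpus, count_dag, ic, ic_threshold=exactly) == 1
    assert go_bp_count("gx", corpus, count_dag, ic,
                       ic_threshold=exactly + 1e-9) == 0


def test_gobp_unknown_gene_counts_zero(count_dag):
    corpus = _count_corpus(count_dag)
    ic = compute_ic(count_dag, corpus, BP)
    assert go_bp_count("nobody", corpus, count_dag, ic) == 0


def test_gobp_ignores_other_namespaces():
    dag = OntologyDAG({
        "R": OntologyTerm("R", "root", BP),
        "M": OntologyTerm("M", "mf", "molecular_function"),
    })
    corpus = AnnotationCorpus("t")
    corpus.add("g1", "R")
    corpus.add("g2", "R")
    corpus.add("gx", "M")
    ic = ICTable({"R": 5.0, "M": 5.0}, 3)
    assert go_bp_count("gx", corpus, dag, ic, ic_threshold=0.0) == 0


def test_gobp_matches_bruteforce_on_random_draws():
    rng = np.random.default_rng(23)
    for _ in range(25):
        dag = random_dag(rng, int(rng.integers(5, 30)))
        corpus = random_corpus(rng, dag, int(rng.integers(3, 15)))
        ic = compute_ic(dag, corpus, BP)
        thr = float(rng.uniform(0, 3))
        for g in sorted(corpus.genes()):
            assert go_bp_count(g, corpus, dag, ic, thr) == \
                brute_force_gobp(dag, corpus.direct_terms(g), ic.ic, thr)


def test_gobp_delta_uses_per_release_ic(count_dag):
    old = _count_corpus(count_dag)
    old.add("gx", "B")
    new = AnnotationCorpus("new", {g: set(a) for g, a
                                   in old.direct_annotations.items()})
    new.add("gx", "C")
    delta = go_bp_delta(old, new, count_dag, count_dag, ["gx"], ic_threshold=2.0)
    assert delta == {"gx": 1}


def test_gobp_delta_requires_genes(count_dag):
    corpus = _count_corpus(count_dag)
    with pytest.raises(ValueError, match="nonempty"):
        go_bp_delta(corpus, corpus, count_dag, count_dag, [])
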