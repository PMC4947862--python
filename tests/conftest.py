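import numpy as np
import pytest

from sappred.ontology import AnnotationCorpus, OntologyDAG, OntologyTerm, BP


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """R <- A <- B (B is_a A is_a R)."""
    return OntologyDAG({
        "R": OntologyTerm("R", "root", BP),
        "A": OntologyTerm("A", "a", BP, frozenset({"R"})),
        "B": OntologyTerm("B", "b", BP, frozenset({"A"})),
    })


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """R <- A, R <- B, A <- C, B <- C."""
    return OntologyDAG({
        "R": OntologyTerm("R", "root", BP),
        "A": OntologyTerm("A", "a", BP, frozenset({"R"})),
        "B": OntologyTerm("B", "b", BP, frozenset({"R"})),
        "C": OntologyTerm("C", "c", BP, frozenset({"A", "B"})),
    })


@pytest.fixture
def small_corpus() -> AnnotationCorpus:
    c = AnnotationCorpus("test")
    c.add("g1", "B", "IDA")
    c.add("g2", "A", "IEA")
    c.add("g3", "R", "IEA")
    return c


def random_corpus(rng: np.random.Generator, dag: OntologyDAG,
                  n_genes: int, mean_terms: float = 2.0) -> AnnotationCorpus:
    corpus = AnnotationCorpus("rand")
    term_ids = sorted(dag.terms)
    for i in range(n_genes):
        k = max(1, int(rng.poisson(mean_terms)))
        for t in rng.choice(len(term_ids), size=min(k, len(term_ids)), replace=False):
            corpus.add(f"g{i}", term_ids[int(t)], "IEA")
    return corpus
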