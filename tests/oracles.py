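"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit enumeration, no shared code
with the package internals beyond the public data types — so tests compare
two independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np

from sappred.ontology import OntologyDAG, OntologyTerm, BP


def random_dag(rng: np.random.Generator, n_terms: int, namespace: str = BP,
               single_root: bool = False) -> OntologyDAG:
    """Random DAG: term i may choose parents among terms < i (acyclic).

    With ``single_root`` every non-first term gets at least one parent, so
    term 0 is the unique root and appears in every annotation closure.
    """
    terms = {}
    ids = [f"T:{i:04d}" for i in range(n_terms)]
    for i, tid in enumerate(ids):
        parents = set()
        if i > 0:
            rootless = not single_root and rng.random() >= 0.9
            n_par = 0 if rootless else int(rng.integers(1, min(i, 3) + 1))
            parents = {ids[int(j)] for j in rng.choice(i, size=min(n_par, i), replace=False)}
        terms[tid] = OntologyTerm(tid, f"t{i}", namespace, frozenset(parents))
    return OntologyDAG(terms)


def reachable_ancestors(dag: OntologyDAG, term_id: str) -> set[str]:
    """Transitive parents by repeated one-step expansion until fixpoint."""
    result: set[str] = set()
    frontier = set(dag.terms[term_id].parent_ids)
    while frontier:
        result |= frontier
        frontier = {p for t in frontier for p in dag.terms[t].parent_ids} - result
    return result


def brute_force_gobp(dag: OntologyDAG, direct_terms: set[str],
                     ic: dict[str, float], threshold: float) -> int:
    """Enumerate-filter-collapse: explicit pairwise ancestor checks."""
    bp_terms = {t for t in direct_terms
                if dag.terms[t].namespace == BP}
    kept = {t for t in bp_terms if t in ic and ic[t] >= threshold}
    survivors = []
    for t in kept:
        has_kept_ancestor = any(other != t and other in reachable_ancestors(dag, t)
                                for other in kept)
        if not has_kept_ancestor:
            survivors.append(t)
    return len(survivors)


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance probability by explicit pair enumeration (ties = 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_best_mcc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Best achievable MCC over thresholds at every distinct score and beyond."""
    def mcc_at(c):
        pred = scores >= c
        tp = np.sum(pred & (labels == 1)); fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1)); tn = np.sum(~pred & (labels == 0))
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        return 0.0 if den == 0 else (tp * tn - fp * fn) / np.sqrt(den)

    cands = list(np.unique(scores)) + [np.max(scores) + 1]
    return max(mcc_at(c) for c in cands)


def two_pass_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation."""
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
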