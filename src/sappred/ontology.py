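"""Gene Ontology style DAGs, information content, and the GO.BP multifunctionality count.

The GO.BP statistic measures gene multifunctionality as the number of distinct
biological processes a gene is annotated with.  Starting from a gene's *direct*
biological-process annotations, two filters make the count non-redundant:

1. terms whose information content (IC) falls below a threshold (default 2.0
   nats) are dropped as non-specific;
2. any remaining term that has another remaining term among its ancestors is
   dropped, because a child term merely specialises its parent rather than
   naming a distinct process.

IC filtering is applied before the child collapse.  IC is the negative natural
log of a term's propagated annotation frequency across the gene corpus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import obonet

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
BP = "biological_process"


class OntologyError(ValueError):
    """Structural problem in an ontology: cycle, dangling reference, bad lookup."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term with its is_a parents."""

    term_id: str
    name: str
    namespace: str
    parent_ids: frozenset[str] = frozenset()


@dataclass
class OntologyDAG:
    """A validated, acyclic is_a hierarchy of :class:`OntologyTerm`.

    ``roots`` are the terms with no parents (one per namespace in a full
    ontology, but any rooted DAG is accepted).
    """

    terms: dict[str, OntologyTerm]

    def __post_init__(self) -> None:
        for t in self.terms.values():
            for p in t.parent_ids:
                if p not in self.terms:
                    raise OntologyError(
                        f"term {t.term_id!r} references missing parent {p!r}"
                    )
        cycle = _find_cycle(self.terms)
        if cycle is not None:
            raise OntologyError(f"ontology contains a cycle through {cycle!r}")

    @property
    def roots(self) -> set[str]:
        return {tid for tid, t in self.terms.items() if not t.parent_ids}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_terms(self, namespace: str) -> set[str]:
        return {tid for tid, t in self.terms.items() if t.namespace == namespace}


def _find_cycle(terms: Mapping[str, OntologyTerm]) -> str | None:
    """Return a member of some is_a cycle, or None. Iterative colouring DFS."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {tid: WHITE for tid in terms}
    for start in terms:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(terms[start].parent_ids))]
        colour[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == GREY:
                    return nxt
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(terms[nxt].parent_ids)))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
    return None


# ---------------------------------------------------------------------------
# OBO subset I/O
# ---------------------------------------------------------------------------

def parse_obo(stream: TextIO | str) -> OntologyDAG:
    """Parse an OBO 1.2 subset ([Term] stanzas with id/name/namespace/is_a).

    Obsolete stanzas are skipped.  Raises :class:`OntologyError` on a dangling
    is_a reference or a cycle, naming the offending identifier.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=True)
    terms: dict[str, OntologyTerm] = {}
    for tid, data in graph.nodes(data=True):
        if "name" not in data and "namespace" not in data:
            # obonet materialises targets of dangling is_a references as
            # attribute-less nodes
            raise OntologyError(f"is_a reference to unknown term {tid!r}")
        parents = frozenset(data.get("is_a", ()))
        terms[tid] = OntologyTerm(
            term_id=tid,
            name=data.get("name", tid),
            namespace=data.get("namespace", BP),
            parent_ids=parents,
        )
    return OntologyDAG(terms)


def write_obo(dag: OntologyDAG, stream: TextIO | None = None) -> str:
    """Serialise a DAG back to the OBO subset read by :func:`parse_obo`."""
    out = io.StringIO()
    out.write("format-version: 1.2\nontology: sappred-synthetic\n")
    for tid in sorted(dag.terms):
        t = dag.terms[tid]
        out.write(f"\n[Term]\nid: {t.term_id}\nname: {t.name}\n")
        out.write(f"namespace: {t.namespace}\n")
        for p in sorted(t.parent_ids):
            out.write(f"is_a: {p}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationCorpus:
    """Direct gene -> (term, evidence_code) annotations for one release.

    All evidence codes are retained; they play no role in any computation here
    but are kept for provenance.
    """

    release_label: str
    direct_annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, gene_id: str, term_id: str, evidence_code: str = "IEA") -> None:
        self.direct_annotations.setdefault(gene_id, set()).add((term_id, evidence_code))

    def genes(self) -> set[str]:
        return set(self.direct_annotations)

    def direct_terms(self, gene_id: str) -> set[str]:
        return {t for t, _ in self.direct_annotations.get(gene_id, ())}

    def validate(self, dag: OntologyDAG) -> None:
        for gene, anns in self.direct_annotations.items():
            for term, _ in anns:
                if term not in dag:
                    raise OntologyError(
                        f"gene {gene!r} annotated to unknown term {term!r}"
                    )

    @classmethod
    def from_table(cls, stream: TextIO | str, release_label: str = "") -> "AnnotationCorpus":
        """Read a headered TSV with columns gene_id, term_id, evidence_code."""
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        header = stream.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("gene_id", "term_id"):
            if col not in idx:
                raise ValueError(f"annotation table missing column {col!r}")
        corpus = cls(release_label=release_label)
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            ev = parts[idx["evidence_code"]] if "evidence_code" in idx else "IEA"
            corpus.add(parts[idx["gene_id"]], parts[idx["term_id"]], ev)
        return corpus

    def to_table(self) -> str:
        rows = ["gene_id\tterm_id\tevidence_code"]
        for gene in sorted(self.direct_annotations):
            for term, ev in sorted(self.direct_annotations[gene]):
                rows.append(f"{gene}\t{term}\t{ev}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Graph queries
# ---------------------------------------------------------------------------

def ancestors(dag: OntologyDAG, term_id: str) -> set[str]:
    """All terms reachable from ``term_id`` via is_a edges, excluding itself."""
    if term_id not in dag:
        raise OntologyError(f"unknown term {term_id!r}")
    seen: set[str] = set()
    frontier = list(dag.terms[term_id].parent_ids)
    while frontier:
        t = frontier.pop()
        if t in seen:
            continue
        seen.add(t)
        frontier.extend(dag.terms[t].parent_ids)
    return seen


def propagate_annotations(dag: OntologyDAG, corpus: AnnotationCorpus) -> dict[str, set[str]]:
    """Annotation closure under the true-path rule.

    Each gene's set is the union of its direct terms and all their ancestors:
    a gene annotated to a term is implicitly annotated to every ancestor.
    """
    corpus.validate(dag)
    anc_cache: dict[str, set[str]] = {}

    def anc(t: str) -> set[str]:
        if t not in anc_cache:
            anc_cache[t] = ancestors(dag, t)
        return anc_cache[t]

    closure: dict[str, set[str]] = {}
    for gene in corpus.genes():
        terms = corpus.direct_terms(gene)
        full = set(terms)
        for t in terms:
            full |= anc(t)
        closure[gene] = full
    return closure


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

@dataclass
class ICTable:
    """Per-term information content in nats, with the corpus size it was
    computed on.  Terms never annotated (directly or via descendants) are
    absent."""

    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def get(self, term_id: str, default: float | None = None) -> float | None:
        return self.ic.get(term_id, default)


def compute_ic(dag: OntologyDAG, corpus: AnnotationCorpus, namespace: str = BP) -> ICTable:
    """IC(t) = -ln(n_t / N) over the propagated annotation closure.

    ``n_t`` counts genes whose closure contains ``t``; ``N`` counts genes with
    at least one propagated annotation in ``namespace``.  The closure makes IC
    anti-monotone along is_a edges: an ancestor covers at least the genes of
    each descendant.
    """
    import math

    ns_terms = dag.namespace_terms(namespace)
    closure = propagate_annotations(dag, corpus)
    counts: dict[str, int] = {}
    n_genes = 0
    for gene, terms in closure.items():
        in_ns = terms & ns_terms
        if not in_ns:
            continue
        n_genes += 1
        for t in in_ns:
            counts[t] = counts.get(t, 0) + 1
    if n_genes == 0:
        raise OntologyError(f"no gene carries a {namespace} annotation")
    ic = {t: -math.log(n / n_genes) for t, n in counts.items()}
    # guard against -0.0 for full-coverage terms
    return ICTable(ic={t: abs(v) if v == 0 else v for t, v in ic.items()},
                   corpus_size=n_genes)


# ---------------------------------------------------------------------------
# GO.BP multifunctionality
# ---------------------------------------------------------------------------

def go_bp_count(
    gene_id: str,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    ic_table: ICTable,
    ic_threshold: float = 2.0,
) -> int:
    """Non-redundant count of a gene's direct biological-process annotations.

    Pipeline: take the gene's unique direct BP terms; drop terms with
    ic < ``ic_threshold`` (boundary kept); then drop any term that has another
    surviving term among its ancestors, at any distance, so that only the most
    general representative of each annotated lineage is counted.  Genes absent
    from the corpus (or with no BP annotation) count 0.
    """
    ns_terms = dag.namespace_terms(BP)
    direct = {t for t in corpus.direct_terms(gene_id) if t in ns_terms}
    if not direct:
        return 0
    # step 1: IC filter (before the child collapse). A direct annotation means
    # n_t >= 1 so the term is present in the table; genes annotated to terms
    # missing from the table can only arise with a foreign IC table, in which
    # case the term is treated as unobserved (IC undefined -> dropped).
    specific = {t for t in direct if ic_table.get(t) is not None
                and ic_table.get(t) >= ic_threshold}
    # step 2: collapse descendants of other surviving terms
    survivors = {t for t in specific if not (ancestors(dag, t) & specific)}
    return len(survivors)


def go_bp_delta(
    corpus_old: AnnotationCorpus,
    corpus_new: AnnotationCorpus,
    dag_old: OntologyDAG,
    dag_new: OntologyDAG,
    gene_ids: Iterable[str],
    ic_threshold: float = 2.0,
) -> dict[str, int]:
    """Per-gene change in GO.BP between two annotation releases.

    Each release uses its own DAG and its own IC table, so both annotation
    growth and ontology restructuring contribute to the difference.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids must be nonempty")
    ic_old = compute_ic(dag_old, corpus_old, BP)
    ic_new = compute_ic(dag_new, corpus_new, BP)
    return {
        g: go_bp_count(g, corpus_new, dag_new, ic_new, ic_threshold)
        - go_bp_count(g, corpus_old, dag_old, ic_old, ic_threshold)
        for g in gene_ids
    }
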