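"""Assembly of the 28-feature SAP matrix.

Sixteen features are variant-level (they depend on the substitution or its
position in the protein) and twelve are gene-level (identical for all SAPs of
one gene).  External predictor scores (SIFT, PROVEAN, PON-P2, GERP, Grantham,
conservation/disorder/accessibility/secondary-structure/Pfam annotations) are
consumed as input columns; the features computed here are the amino-acid-index
deltas, the tissue-expression fraction, the interaction-network measures
(degree, alpha centrality, betweenness), the paralog/ortholog summaries, and
the GO.BP multifunctionality count supplied by the ontology module.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: orientation: how a numeric score relates to pathogenicity when used
#: directly as a classifier ("higher_pathogenic" means larger values indicate
#: a pathogenic variant).
HIGHER_PATHOGENIC = "higher_pathogenic"
LOWER_PATHOGENIC = "lower_pathogenic"
UNORIENTED = "unoriented"


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str        # numeric | categorical
    level: str       # variant | gene
    orientation: str = UNORIENTED


#: The 28 features of the analysis, in canonical order.
FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("PON-P2", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("SIFT", "numeric", "variant", LOWER_PATHOGENIC),
    FeatureSpec("PROVEAN", "numeric", "variant", LOWER_PATHOGENIC),
    FeatureSpec("Grantham", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("GERP", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("evolutionary.rate", "numeric", "variant", LOWER_PATHOGENIC),
    FeatureSpec("disordered.region", "numeric", "variant", LOWER_PATHOGENIC),
    FeatureSpec("accessibility", "numeric", "variant", LOWER_PATHOGENIC),
    FeatureSpec("secondary.structure.3", "categorical", "variant"),
    FeatureSpec("secondary.structure.8", "categorical", "variant"),
    FeatureSpec("PfamA", "categorical", "variant"),
    FeatureSpec("AAindex.polarity", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("AAindex.hydropathy", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("AAindex.volume", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("AAindex.composition", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("AAindex.net.charge", "numeric", "variant", HIGHER_PATHOGENIC),
    FeatureSpec("protein.age", "numeric", "gene", HIGHER_PATHOGENIC),
    FeatureSpec("paralog.id", "numeric", "gene", UNORIENTED),
    FeatureSpec("paralog.nr", "numeric", "gene", UNORIENTED),
    FeatureSpec("mouse.orth.id", "numeric", "gene", UNORIENTED),
    FeatureSpec("mouse.orth.nr", "numeric", "gene", UNORIENTED),
    FeatureSpec("GO.BP", "numeric", "gene", HIGHER_PATHOGENIC),
    FeatureSpec("expression", "numeric", "gene", UNORIENTED),
    FeatureSpec("degree", "numeric", "gene", HIGHER_PATHOGENIC),
    FeatureSpec("centrality", "numeric", "gene", HIGHER_PATHOGENIC),
    FeatureSpec("betweenness", "numeric", "gene", HIGHER_PATHOGENIC),
    FeatureSpec("gene.length", "numeric", "gene", UNORIENTED),
    FeatureSpec("protein.length", "numeric", "gene", UNORIENTED),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
NUMERIC_FEATURES: tuple[str, ...] = tuple(f.name for f in FEATURES if f.kind == "numeric")
GENE_LEVEL_FEATURES: tuple[str, ...] = tuple(f.name for f in FEATURES if f.level == "gene")
ORIENTATION: dict[str, str] = {f.name: f.orientation for f in FEATURES}

#: Kyte-Doolittle hydropathy (AAindex KYTJ820101), used as the worked example
#: amino-acid index and by the synthetic generator.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def aaindex_delta(ref_aa: str, alt_aa: str, index_values: dict[str, float]) -> float:
    """Absolute difference of an amino-acid index between original and mutant."""
    for aa in (ref_aa, alt_aa):
        if aa not in index_values:
            raise KeyError(f"amino acid {aa!r} not in index")
    return abs(index_values[ref_aa] - index_values[alt_aa])


def expression_fraction(expr_row: np.ndarray | pd.Series, threshold: float) -> float:
    """Fraction of tissues in which the gene is expressed at ``threshold``."""
    values = np.asarray(expr_row, dtype=float)
    if values.size == 0:
        raise ValueError("expression row is empty")
    return float(np.mean(values >= threshold))


def derive_expression_threshold(expr_matrix: pd.DataFrame) -> float:
    """Mean over genes of the first quartile of each gene's tissue values.

    Quartiles use linear interpolation (numpy default / R type 7), the
    convention applied throughout the package.
    """
    q1 = expr_matrix.quantile(0.25, axis=1, interpolation="linear")
    return float(q1.mean())


def network_features(
    edges: pd.DataFrame,
    confidence_cutoff_quantile: float = 0.25,
    alpha: float = 0.9,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Degree, alpha centrality, and betweenness on the confidence-filtered network.

    Edges with confidence below the ``confidence_cutoff_quantile`` quantile of
    the full confidence distribution (linear-interpolation quantile) are
    discarded; the rest form an undirected simple graph.  Alpha centrality
    solves x = alpha * A x + e with exogenous input e = 1 per node; damping
    ``alpha`` defaults to 0.9, scaled internally to alpha/lambda_max when the
    graph's spectral radius would make I - alpha*A singular or the solution
    sign-unstable.  Betweenness is unnormalised shortest-path betweenness.
    Genes listed in ``genes`` but absent from the filtered network get 0 for
    all three measures.
    """
    cutoff = float(np.quantile(edges["confidence"].to_numpy(dtype=float),
                               confidence_cutoff_quantile))
    kept = edges[edges["confidence"] >= cutoff]
    g = nx.Graph()
    g.add_edges_from(zip(kept["gene_a"], kept["gene_b"]))
    g.remove_edges_from(nx.selfloop_edges(g))

    if g.number_of_nodes():
        a = nx.to_numpy_array(g)
        lam = float(np.max(np.abs(np.linalg.eigvals(a)))) if a.size else 0.0
        eff_alpha = alpha if lam == 0 or alpha < 1.0 / lam else 0.9 / lam
        n = a.shape[0]
        x = np.linalg.solve(np.eye(n) - eff_alpha * a.T, np.ones(n))
        cent = dict(zip(g.nodes, x))
        betw = nx.betweenness_centrality(g, normalized=False)
    else:
        cent, betw = {}, {}

    index = list(genes) if genes is not None else list(g.nodes)
    rows = []
    for gene in index:
        if gene in g:
            rows.append((g.degree(gene), cent[gene], betw[gene]))
        else:
            rows.append((0, 0.0, 0.0))
    return pd.DataFrame(rows, index=index, columns=["degree", "centrality", "betweenness"])


def homolog_summary(records: pd.DataFrame) -> tuple[int, float]:
    """(count, max identity) over homolog records with confidence one.

    Genes without any confident homolog get (0, 0).
    """
    if len(records) == 0:
        return 0, 0.0
    confident = records[records["confidence"] == 1]
    if len(confident) == 0:
        return 0, 0.0
    return len(confident), float(confident["identity"].max())


def assemble_matrix(
    saps: pd.DataFrame,
    score_columns: pd.DataFrame | None = None,
    gene_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per SAP: label plus the 28 feature columns.

    ``score_columns`` is indexed by sap_key (variant-level features);
    ``gene_features`` by gene_id (gene-level features, broadcast to every SAP
    of the gene).  Features supplied by neither source become all-missing
    columns.  A gene-level table with duplicate, conflicting rows for one gene
    raises a consistency error.
    """
    out = saps.set_index("sap_key")[["gene_id", "label"]].copy()
    if score_columns is not None:
        for col in score_columns.columns:
            out[col] = score_columns[col].reindex(out.index)
    if gene_features is not None:
        if gene_features.index.duplicated().any():
            dup = gene_features.index[gene_features.index.duplicated()][0]
            if not (gene_features.loc[[dup]].nunique() <= 1).all():
                raise ValueError(f"conflicting gene-level values for gene {dup!r}")
            gene_features = gene_features[~gene_features.index.duplicated()]
        for col in gene_features.columns:
            out[col] = gene_features[col].reindex(out["gene_id"]).to_numpy()
    for name in FEATURE_NAMES:
        if name not in out.columns:
            out[name] = np.nan
    return out[["gene_id", "label", *FEATURE_NAMES]]


def complete_cases(matrix: pd.DataFrame, feature_subset: list[str]) -> pd.DataFrame:
    """Rows with no missing value in ``feature_subset``.

    Raises with a per-feature missingness report when nothing survives.
    """
    unknown = [f for f in feature_subset if f not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown features {unknown}")
    keep = matrix[list(feature_subset)].notna().all(axis=1)
    result = matrix[keep]
    if len(result) == 0:
        report = matrix[list(feature_subset)].isna().mean().to_dict()
        raise ValueError(f"no complete cases; per-feature missingness: {report}")
    return result
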