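"""Downstream characterisation: systematically misclassified SAPs and the
annotation-bias comparison between ontology releases.

A "difficult" SAP is one misclassified by every compared method at its
operating cutoff — separately for false positives (benign predicted
pathogenic) and false negatives (pathogenic predicted benign).  Genes whose
difficult-FN frequency exceeds the expected error rate are flagged.

The bias analysis asks whether knowing a gene harbours disease variants
inflates its later annotation growth: genes are grouped by when their first
disease variant was reported (period A / period B / never) and the per-group
growth in the GO.BP multifunctionality count between two annotation releases
is compared by one-sided t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import AnnotationCorpus, OntologyDAG, go_bp_delta


@dataclass
class MethodPredictions:
    """Per-SAP predicted labels of one method at its cutoff, with truth."""

    name: str
    predictions: pd.Series  # sap_key -> predicted label ("pathogenic"/"benign")
    truth: pd.Series        # sap_key -> true label

    @classmethod
    def from_scores(cls, name, sap_keys, scores, labels, cutoff) -> "MethodPredictions":
        scores = np.asarray(scores, dtype=float)
        pred = np.where(scores >= cutoff, "pathogenic", "benign")
        return cls(name,
                   pd.Series(pred, index=sap_keys),
                   pd.Series(np.asarray(labels), index=sap_keys))


def false_sets(predictions: list[MethodPredictions]) -> dict[str, tuple[set, set]]:
    """Per-method (false-positive set, false-negative set) of sap_keys."""
    universe = set(predictions[0].predictions.index)
    truth0 = predictions[0].truth
    out = {}
    for m in predictions:
        if set(m.predictions.index) != universe:
            raise ValueError(f"method {m.name!r} scores a different SAP universe")
        if not m.truth.reindex(truth0.index).equals(truth0):
            raise ValueError(f"method {m.name!r} disagrees on true labels")
        fp = set(m.predictions.index[(m.predictions == "pathogenic")
                                     & (m.truth == "benign")])
        fn = set(m.predictions.index[(m.predictions == "benign")
                                     & (m.truth == "pathogenic")])
        out[m.name] = (fp, fn)
    return out


def _venn_counts(sets: dict[str, set]) -> dict[frozenset, int]:
    """Count of items in each exclusive region of the Venn diagram."""
    membership: dict[str, frozenset] = {}
    for name, s in sets.items():
        for item in s:
            membership[item] = membership.get(item, frozenset()) | {name}
    counts: dict[frozenset, int] = {}
    for region in membership.values():
        counts[region] = counts.get(region, 0) + 1
    return counts


def difficult_saps(
    per_method_sets: dict[str, tuple[set, set]],
) -> tuple[set, set, dict[frozenset, int], dict[frozenset, int]]:
    """Intersection of error sets over all methods, plus Venn region counts.

    Returns (difficult FP, difficult FN, FP Venn counts, FN Venn counts);
    region keys are frozensets of method names and count only SAPs belonging
    to exactly that set of methods' error sets.
    """
    if len(per_method_sets) < 2:
        raise ValueError("need at least 2 methods")
    fps = {m: s[0] for m, s in per_method_sets.items()}
    fns = {m: s[1] for m, s in per_method_sets.items()}
    diff_fp = set.intersection(*fps.values())
    diff_fn = set.intersection(*fns.values())
    return diff_fp, diff_fn, _venn_counts(fps), _venn_counts(fns)


def rescue_fractions(per_method_sets: dict[str, tuple[set, set]]) -> pd.DataFrame:
    """Per method: share of its errors that are difficult vs rescued.

    A SAP is "rescued" when at least one other method predicts it correctly;
    per error type the rescued fraction is 1 minus the difficult share.
    """
    diff_fp, diff_fn, _, _ = difficult_saps(per_method_sets)
    rows = []
    for m, (fp, fn) in per_method_sets.items():
        rows.append({
            "method": m,
            "n_fp": len(fp),
            "difficult_fp_share": len(diff_fp) / len(fp) if fp else float("nan"),
            "n_fn": len(fn),
            "difficult_fn_share": len(diff_fn) / len(fn) if fn else float("nan"),
        })
    df = pd.DataFrame(rows)
    df["rescued_fp_share"] = 1 - df["difficult_fp_share"]
    df["rescued_fn_share"] = 1 - df["difficult_fn_share"]
    return df


def gene_fn_excess(
    difficult_fns: set,
    saps_per_gene: pd.Series,
    gene_of: pd.Series,
    expected_rate: float = 0.05,
    min_difficult: int = 2,
) -> pd.DataFrame:
    """Genes whose difficult-FN frequency exceeds the expected error rate.

    ``saps_per_gene`` gives each gene's total SAP count in the evaluation set;
    ``gene_of`` maps sap_key -> gene.  A gene is flagged when it has at least
    ``min_difficult`` difficult SAPs and difficult-FN count / total SAPs
    exceeds ``expected_rate``.
    """
    counts: dict[str, int] = {}
    for sap in difficult_fns:
        g = gene_of.get(sap)
        if g is not None:
            counts[g] = counts.get(g, 0) + 1
    rows = []
    for g, n_fn in sorted(counts.items()):
        total = int(saps_per_gene.get(g, 0))
        freq = n_fn / total if total else float("nan")
        if n_fn >= min_difficult and total and freq > expected_rate:
            rows.append({"gene_id": g, "difficult_fn": n_fn,
                         "total_saps": total, "fn_frequency": freq})
    return pd.DataFrame(rows, columns=["gene_id", "difficult_fn",
                                       "total_saps", "fn_frequency"])


@dataclass
class BiasGroups:
    """Disjoint gene groups by the period of their first disease report."""

    group1: set[str]  # first disease variant reported in period A
    group2: set[str]  # first disease variant reported in period B
    group3: set[str]  # no disease variant ever reported

    def __post_init__(self) -> None:
        if (self.group1 & self.group2) or (self.group1 & self.group3) \
                or (self.group2 & self.group3):
            raise ValueError("bias groups must be pairwise disjoint")


def assign_bias_groups(
    first_report_year: dict[str, int | None],
    year_a: int,
    year_b: int,
    all_genes: set[str] | None = None,
) -> BiasGroups:
    """Partition genes by first-disease-report year.

    ``first_report_year`` maps gene -> year of its first disease variant
    (None/absent = never reported).  ``all_genes`` (default: the map's keys)
    defines the protein-coding universe for the never-reported group.
    """
    genes = set(all_genes) if all_genes is not None else set(first_report_year)
    g1 = {g for g in genes if first_report_year.get(g) == year_a}
    g2 = {g for g in genes if first_report_year.get(g) == year_b}
    g3 = {g for g in genes if first_report_year.get(g) is None}
    return BiasGroups(g1, g2, g3)


def one_sided_t_test(x, y) -> tuple[float, int, float]:
    """Pooled-variance Student t-test of mean(x) > mean(y).

    Returns (t, df, one-sided upper-tail p).  Raises on zero pooled variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    df = len(x) + len(y) - 2
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    p = float(stats.t.sf(t, df))
    return float(t), int(df), p


def bias_analysis(
    corpus_old: AnnotationCorpus,
    corpus_new: AnnotationCorpus,
    dag_old: OntologyDAG,
    dag_new: OntologyDAG,
    groups: BiasGroups,
    ic_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-group GO.BP release deltas with the two one-sided comparisons.

    Tests group1 > group2 (knowledge-driven follow-up bias) and
    group2 > group3 (multifunctionality as a true disease-gene property).
    Degenerate comparisons (zero pooled variance, e.g. identical releases)
    are flagged in the ``degenerate`` column rather than raising.
    """
    named = {"group1": groups.group1, "group2": groups.group2, "group3": groups.group3}
    for name, g in named.items():
        if not g:
            raise ValueError(f"{name} is empty")
    deltas = {
        name: np.array(list(go_bp_delta(
            corpus_old, corpus_new, dag_old, dag_new, sorted(g), ic_threshold
        ).values()), dtype=float)
        for name, g in named.items()
    }
    rows = []
    for a, b in (("group1", "group2"), ("group2", "group3")):
        row = {
            "comparison": f"{a}>{b}",
            "n_a": len(deltas[a]), "n_b": len(deltas[b]),
            "mean_a": float(deltas[a].mean()), "mean_b": float(deltas[b].mean()),
            "sd_a": float(deltas[a].std(ddof=1)) if len(deltas[a]) > 1 else float("nan"),
            "sd_b": float(deltas[b].std(ddof=1)) if len(deltas[b]) > 1 else float("nan"),
        }
        try:
            t, df, p = one_sided_t_test(deltas[a], deltas[b])
            row.update(t=t, df=df, p=p, degenerate=False)
        except ValueError:
            row.update(t=float("nan"), df=len(deltas[a]) + len(deltas[b]) - 2,
                       p=float("nan"), degenerate=True)
        rows.append(row)
    return pd.DataFrame(rows)
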