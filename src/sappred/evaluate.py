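"""Classifier evaluation: ROC and precision-recall curves, tie-aware AUC,
paired bootstrap AUC comparison, and MCC-optimal operating points.

All scores are assumed oriented so that higher values indicate pathogenicity;
the classification rule at threshold t is "score >= t => pathogenic".  AUC is
computed as the concordance probability P(score_pathogenic > score_benign)
with ties counting one half, which equals the trapezoidal area under the ROC
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_scored(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> pd.DataFrame:
    """Sensitivity/specificity over all distinct thresholds (rule: score >= t).

    Includes a threshold above every score (sens 0, spec 1); the lowest
    distinct score yields the (sens 1, spec 0)-ward end of the curve.
    """
    scores, labels = _check_scored(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    sens, spec = [], []
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        sens.append(tp / n_pos)
        spec.append((n_neg - fp) / n_neg)
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sens,
                         "specificity": spec})


def auc(scores, labels) -> float:
    """Tie-aware concordance probability via the rank-sum identity."""
    scores, labels = _check_scored(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # midranks handle ties
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def bootstrap_auc_test(
    scores_a, scores_b, labels, n_boot: int = 5000, seed: int = 0
) -> tuple[float, float]:
    """Paired, class-stratified bootstrap test for a difference in AUC.

    Both score vectors must be computed on the same SAPs (paired design).
    Resamples SAPs within each class, recomputes both AUCs per replicate, and
    derives a two-sided p-value from the bootstrap distribution of the AUC
    difference D: with observed difference d and bootstrap standard deviation
    s, p = 2 * (1 - Phi(|d| / s)) (the normal-quantile convention of the
    standard paired-bootstrap ROC comparison).  Returns (delta_auc, p_value).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired test requires identical SAP sets for both scores")
    delta = auc(scores_a, labels) - auc(scores_b, labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos_idx, size=len(pos_idx)),
                              rng.choice(neg_idx, size=len(neg_idx))])
        lab = labels[idx]
        diffs[b] = auc_unchecked(scores_a[idx], lab) - auc_unchecked(scores_b[idx], lab)
    s = float(diffs.std(ddof=1))
    if s == 0:
        return delta, 1.0
    p = float(2 * norm.sf(abs(delta) / s))
    return delta, min(p, 1.0)


def auc_unchecked(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC without validation, for hot loops (both classes assumed present)."""
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return (float(ranks[labels == 1].sum()) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def confusion_at(scores, labels, cutoff: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def best_mcc_cutoff(scores, labels) -> tuple[float, float]:
    """Cutoff maximising MCC, evaluated at midpoints between distinct scores.

    Candidate cutoffs are the midpoints between consecutive sorted distinct
    scores plus sentinels below and above all scores; ties in MCC go to the
    smallest cutoff.
    """
    scores, labels = _check_scored(scores, labels)
    distinct = np.unique(scores)
    candidates = [distinct[0] - 1.0]
    candidates += list((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(distinct[-1] + 1.0)
    best_c, best_m = candidates[0], -2.0
    for c in candidates:
        m = mcc(confusion_at(scores, labels, c))
        if m > best_m:
            best_c, best_m = c, m
    return float(best_c), float(best_m)


def metrics_at_cutoff(scores, labels, cutoff: float) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV, NPV, and MCC at one cutoff.

    Ratios with zero denominators are reported as NaN.
    """
    c = confusion_at(scores, labels, cutoff)

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "cutoff": float(cutoff),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "accuracy": ratio(c.tp + c.tn, c.n),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "mcc": mcc(c),
    }


def sensitivity_at_specificity(scores, labels, target_spec: float = 0.86) -> float:
    """Sensitivity at the smallest achievable specificity >= target.

    Step convention: reads the ROC curve point, no interpolation.
    """
    curve = roc_curve(scores, labels)
    ok = curve[curve["specificity"] >= target_spec]
    if len(ok) == 0:
        return 0.0
    best = ok.loc[ok["specificity"].idxmin()]
    # among thresholds achieving that specificity, take the highest sensitivity
    at = ok[ok["specificity"] == best["specificity"]]
    return float(at["sensitivity"].max())


def precision_recall_curve(scores, labels) -> pd.DataFrame:
    """Precision/recall over the same thresholds as the ROC curve."""
    scores, labels = _check_scored(scores, labels)
    n_pos = int(labels.sum())
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    prec, rec = [], []
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        prec.append(tp / (tp + fp) if tp + fp > 0 else float("nan"))
        rec.append(tp / n_pos)
    return pd.DataFrame({"threshold": thresholds, "precision": prec, "recall": rec})


def evaluation_report(
    scored: dict[str, tuple[np.ndarray, np.ndarray]],
    cutoffs: dict[str, float] | None = None,
    n_boot: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranked metric panel over several classifiers on one SAP universe.

    ``scored`` maps classifier name -> (scores, labels); all label vectors
    must be identical (paired comparisons).  Cutoffs default to each
    classifier's MCC-optimal cutoff; fixed cutoffs (e.g. a method developer's
    published threshold) can be supplied per name.  Classifiers are ordered
    by AUC, and each is compared with the next best by the paired bootstrap
    test.
    """
    names = list(scored)
    labels0 = np.asarray(scored[names[0]][1], dtype=int)
    for name in names[1:]:
        if not np.array_equal(np.asarray(scored[name][1], dtype=int), labels0):
            raise ValueError("all classifiers must score the same labeled SAPs")
    rows = []
    for name in names:
        s, y = scored[name]
        if cutoffs is not None and name in cutoffs:
            cut = cutoffs[name]
            best_m = metrics_at_cutoff(s, y, cut)["mcc"]
        else:
            cut, best_m = best_mcc_cutoff(s, y)
        panel = metrics_at_cutoff(s, y, cut)
        panel["classifier"] = name
        panel["auc"] = auc(s, y)
        rows.append(panel)
    report = pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    pvals, deltas = [], []
    for i in range(len(report)):
        if i + 1 < len(report):
            a = report.loc[i, "classifier"]
            b = report.loc[i + 1, "classifier"]
            d, p = bootstrap_auc_test(scored[a][0], scored[b][0], labels0,
                                      n_boot=n_boot, seed=seed + i)
            deltas.append(d)
            pvals.append(p)
        else:
            deltas.append(float("nan"))
            pvals.append(float("nan"))
    report["delta_auc_next"] = deltas
    report["p_vs_next"] = pvals
    report["significant_vs_next"] = report["p_vs_next"] < 0.05
    cols = ["classifier", "cutoff", "sensitivity", "specificity", "accuracy",
            "ppv", "npv", "mcc", "auc", "delta_auc_next", "p_vs_next",
            "significant_vs_next"]
    return report[cols]
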