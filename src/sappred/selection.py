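"""Classifier fitting and cross-validated forward feature selection.

The selection protocol works under gene-aware folds: every cross-validation
boundary keeps all SAPs of a gene on one side, so gene-level features cannot
leak between training and testing.  Two rankers are supported:

* logistic regression — one additive model on all candidate features, features
  ordered by ascending Wald-z p-value;
* random forest — features ordered by descending permutation importance.

For each CV fold the features are ranked on the fold's training portion, then
the nested prefixes (first 1, 2, ... features) are fit and scored on the
held-out fold: logistic regression with the mean squared residual of its
probability predictions, random forests with the misclassification rate.
The selected feature set is the smallest prefix whose mean test error is
within one standard error of the global minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.tree import DecisionTreeClassifier

from .datasets import gene_aware_folds
from .features import complete_cases

#: The combinations selected by the three-stage protocol (raw features only /
#: raw + rule prediction scores / all features).
PFS1: tuple[str, ...] = ("GO.BP", "evolutionary.rate", "disordered.region")
PFS2: tuple[str, ...] = ("GO.BP", "PROVEAN", "SIFT", "GERP", "disordered.region")
PFS3: tuple[str, ...] = ("PON-P2", "GO.BP", "PROVEAN")
PFS_SETS: dict[str, tuple[str, ...]] = {"PFS1": PFS1, "PFS2": PFS2, "PFS3": PFS3}

LABEL_CODE = {"benign": 0, "pathogenic": 1}


def _xy(matrix: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, np.ndarray]:
    x = matrix[list(features)].to_numpy(dtype=float)
    y = matrix["label"].map(LABEL_CODE).to_numpy(dtype=int)
    return x, y


@dataclass
class FittedClassifier:
    kind: str                      # decision_tree | logistic | random_forest
    features: tuple[str, ...]
    model: object
    seed: int | None = None

    def predict_proba(self, matrix: pd.DataFrame) -> pd.Series:
        """Probability of the pathogenic class for each row."""
        x = matrix[list(self.features)].to_numpy(dtype=float)
        if self.kind == "logistic":
            p = self.model.predict(x)
        else:
            p = self.model.predict_proba(x)[:, 1]
        return pd.Series(np.asarray(p, dtype=float), index=matrix.index)


def fit_decision_tree(
    matrix: pd.DataFrame, features: list[str], seed: int = 0, **tree_kwargs
) -> tuple[FittedClassifier, pd.DataFrame]:
    """CART-style tree (Gini) plus a per-node summary.

    The summary gives, per node, the class fractions and the fraction of all
    training SAPs reaching the node — the quantities one reads off a printed
    rule tree.  Default pruning: ``min_samples_leaf=20, ccp_alpha=0.003``
    (interpretability-oriented; configurable through ``tree_kwargs``).
    """
    data = complete_cases(matrix, list(features))
    x, y = _xy(data, list(features))
    if len(np.unique(y)) < 2:
        raise ValueError("decision tree requires both classes present")
    kwargs = dict(criterion="gini", min_samples_leaf=20, ccp_alpha=0.003,
                  random_state=seed)
    kwargs.update(tree_kwargs)
    model = DecisionTreeClassifier(**kwargs).fit(x, y)
    t = model.tree_
    rows = []
    total = t.n_node_samples[0]
    for node in range(t.node_count):
        counts = t.value[node][0] * t.n_node_samples[node] / max(t.value[node][0].sum(), 1)
        frac = t.value[node][0] / t.value[node][0].sum()
        rows.append({
            "node": node,
            "feature": features[t.feature[node]] if t.children_left[node] != -1 else "",
            "threshold": t.threshold[node] if t.children_left[node] != -1 else np.nan,
            "frac_benign": frac[0] if len(frac) > 1 else 1.0,
            "frac_pathogenic": frac[1] if len(frac) > 1 else 0.0,
            "coverage": t.n_node_samples[node] / total,
            "is_leaf": t.children_left[node] == -1,
        })
        del counts
    clf = FittedClassifier("decision_tree", tuple(features), model, seed)
    return clf, pd.DataFrame(rows)


@dataclass
class LogitFit:
    """Coefficients and Wald statistics of one logistic fit (intercept first)."""

    params: np.ndarray
    bse: np.ndarray
    ridge_fallback: bool = False

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm
        with np.errstate(invalid="ignore", divide="ignore"):
            z = self.params / self.bse
        return 2 * norm.sf(np.abs(z))

    def predict(self, x: np.ndarray) -> np.ndarray:
        eta = self.params[0] + x @ self.params[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float = 1e-3,
                 maxiter: int = 50) -> LogitFit:
    """Ridge-penalised IRLS; the documented fallback when the unpenalised
    likelihood is unbounded (perfect separation). Intercept unpenalised."""
    xc = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(xc.shape[1])
    pen = np.eye(xc.shape[1])
    pen[0, 0] = 0.0
    h = None
    for _ in range(maxiter):
        p = 1.0 / (1.0 + np.exp(-np.clip(xc @ beta, -35, 35)))
        w = p * (1 - p) + 1e-10
        h = xc.T @ (xc * w[:, None]) + alpha * pen
        g = xc.T @ (y - p) - alpha * (pen @ beta)
        step = np.linalg.solve(h, g)
        beta += step
        if np.max(np.abs(step)) < 1e-8:
            break
    bse = np.sqrt(np.diag(np.linalg.inv(h)))
    return LogitFit(beta, bse, ridge_fallback=True)


def _fit_logit(x: np.ndarray, y: np.ndarray) -> LogitFit:
    """Unregularised ML logistic fit with a small-ridge fallback on separation."""
    xc = sm.add_constant(x, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, xc).fit(disp=0, maxiter=100)
        if not (np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))
                and np.all(res.bse < 1e4)):
            raise np.linalg.LinAlgError("unstable standard errors")
        return LogitFit(np.asarray(res.params), np.asarray(res.bse))
    except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
        return _ridge_logit(x, y)


def rank_features_logistic(matrix: pd.DataFrame, features: list[str]) -> list[str]:
    """Order features by ascending Wald-z p-value of one additive logistic fit.

    Ties (and features with undefined standard errors) break lexicographically,
    so the ranking is always a total order.
    """
    features = list(features)
    data = complete_cases(matrix, features)
    x, y = _xy(data, features)
    res = _fit_logit(x, y)
    p = np.asarray(res.pvalues)[1:]  # skip intercept
    p = np.where(np.isfinite(p), p, 1.0)
    order = sorted(range(len(features)), key=lambda i: (p[i], features[i]))
    return [features[i] for i in order]


def rank_features_forest(
    matrix: pd.DataFrame, features: list[str], seed: int = 0,
    n_estimators: int = 500, n_repeats: int = 1,
    max_samples: float | None = None,
) -> list[str]:
    """Order features by descending permutation importance of one forest fit.

    Importance is the drop in accuracy when a feature column is permuted
    (seeded), measured on the training sample of the fitted forest.  Ties
    break lexicographically.
    """
    features = list(features)
    data = complete_cases(matrix, features)
    x, y = _xy(data, features)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed,
        n_jobs=1, max_samples=max_samples,
    ).fit(x, y)
    imp = permutation_importance(
        forest, x, y, n_repeats=n_repeats, random_state=seed, n_jobs=1
    ).importances_mean
    order = sorted(range(len(features)), key=lambda i: (-imp[i], features[i]))
    return [features[i] for i in order]


@dataclass
class SelectionTrace:
    """Per-step aggregate of the forward-selection cross-validation."""

    ranker: str
    iterations: int
    folds: int
    seed: int
    steps: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: fraction of (iteration, fold) rankings placing each feature at each
    #: step ("step identity") and within the first k steps ("first-k").
    step_frequency: pd.DataFrame = field(default_factory=pd.DataFrame)
    first_k_frequency: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_table(self) -> pd.DataFrame:
        return self.steps.copy()


def _prefix_errors_logistic(train, test, ranked, max_steps):
    """Mean squared residual of probability predictions per nested prefix."""
    errs_tr, errs_te = [], []
    x_tr, y_tr = _xy(train, ranked)
    x_te, y_te = _xy(test, ranked)
    for m in range(1, min(len(ranked), max_steps) + 1):
        res = _fit_logit(x_tr[:, :m], y_tr)
        errs_tr.append(float(np.mean((y_tr - res.predict(x_tr[:, :m])) ** 2)))
        errs_te.append(float(np.mean((y_te - res.predict(x_te[:, :m])) ** 2)))
    return errs_tr, errs_te


def _prefix_errors_forest(train, test, ranked, seed, n_estimators, max_steps,
                          max_samples=None):
    """Misclassification rate per nested prefix."""
    errs_tr, errs_te = [], []
    x_tr, y_tr = _xy(train, ranked)
    x_te, y_te = _xy(test, ranked)
    for m in range(1, min(len(ranked), max_steps) + 1):
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            random_state=seed, n_jobs=1, max_samples=max_samples,
        ).fit(x_tr[:, :m], y_tr)
        errs_tr.append(float(np.mean(forest.predict(x_tr[:, :m]) != y_tr)))
        errs_te.append(float(np.mean(forest.predict(x_te[:, :m]) != y_te)))
    return errs_tr, errs_te


def forward_selection(
    matrix: pd.DataFrame,
    features: list[str],
    ranker: str = "logistic",
    k: int = 5,
    iterations: int = 20,
    seed: int = 0,
    n_estimators: int = 100,
    max_steps: int | None = None,
    max_samples: float | None = None,
    max_resample: int = 20,
) -> SelectionTrace:
    """Cross-validated forward selection under gene-aware folds.

    Per iteration, SAPs are dealt into ``k`` gene-aware folds with a fresh
    randomisation; per fold, features are ranked on the training portion and
    the nested prefixes scored on the held-out fold.  Returns per-step error
    means/sds and per-step selection frequencies.  An iteration producing a
    single-class fold is resampled (and counted against ``max_resample``).

    ``max_steps`` caps how many nested prefixes are evaluated (the error
    curve is read over its first steps; evaluating every prefix of a large
    pool adds nothing to the stopping decision).  ``max_samples`` is the
    bootstrap subsample fraction per forest tree.
    """
    if ranker not in ("logistic", "random_forest"):
        raise ValueError(f"unknown ranker {ranker!r}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    features = list(features)
    data = complete_cases(matrix, features).reset_index()
    n_feat = len(features)
    n_steps = n_feat if max_steps is None else min(max_steps, n_feat)
    rng = np.random.default_rng(seed)

    err_train = np.zeros((iterations * k, n_steps))
    err_test = np.zeros((iterations * k, n_steps))
    step_counts = np.zeros((n_feat, n_feat))  # [feature, step]
    row = 0
    feat_index = {f: i for i, f in enumerate(features)}

    for it in range(iterations):
        for attempt in range(max_resample):
            fold_seed = int(rng.integers(0, 2**31 - 1))
            folds = gene_aware_folds(data, k=k, seed=fold_seed)
            fold_of = folds.reindex(data["sap_key"]).to_numpy()
            ok = all(
                data.loc[fold_of != f, "label"].nunique() == 2
                and data.loc[fold_of == f, "label"].nunique() == 2
                for f in range(k)
            )
            if ok:
                break
        else:
            raise RuntimeError("could not build two-class gene-aware folds")
        for f in range(k):
            train = data[fold_of != f]
            test = data[fold_of == f]
            if ranker == "logistic":
                ranked = rank_features_logistic(train, features)
                e_tr, e_te = _prefix_errors_logistic(train, test, ranked, n_steps)
            else:
                rseed = int(rng.integers(0, 2**31 - 1))
                ranked = rank_features_forest(
                    train, features, seed=rseed, n_estimators=n_estimators,
                    max_samples=max_samples)
                e_tr, e_te = _prefix_errors_forest(
                    train, test, ranked, rseed, n_estimators, n_steps,
                    max_samples)
            err_train[row] = e_tr
            err_test[row] = e_te
            for step, feat in enumerate(ranked):
                step_counts[feat_index[feat], step] += 1
            row += 1

    n_eval = iterations * k
    steps = pd.DataFrame({
        "step": np.arange(1, n_steps + 1),
        "mean_train_error": err_train.mean(axis=0),
        "sd_train_error": err_train.std(axis=0, ddof=1),
        "mean_test_error": err_test.mean(axis=0),
        "sd_test_error": err_test.std(axis=0, ddof=1),
    })
    freq = step_counts / n_eval
    step_freq = pd.DataFrame(freq, index=features,
                             columns=[f"step{i+1}" for i in range(n_feat)])
    firstk = pd.DataFrame(np.cumsum(freq, axis=1), index=features,
                          columns=[f"first{i+1}" for i in range(n_feat)])
    # the modal feature of each step names the step in the trace table
    steps["feature"] = [features[int(np.argmax(step_counts[:, s]))]
                        for s in range(n_steps)]
    steps["selection_frequency"] = [float(np.max(freq[:, s])) for s in range(n_steps)]
    return SelectionTrace(
        ranker=ranker, iterations=iterations, folds=k, seed=seed,
        steps=steps, step_frequency=step_freq, first_k_frequency=firstk,
    )


def choose_prefix(trace: SelectionTrace) -> tuple[str, ...]:
    """Smallest prefix whose mean test error is within one SE of the minimum.

    The standard error is the per-step sd over all (iteration, fold)
    evaluations divided by sqrt of their number; this formalises the "error
    went up again, stop" judgment of a manual read of the error curve.
    Returns the features in the trace's modal step order.
    """
    steps = trace.steps
    if len(steps) == 0:
        raise ValueError("empty selection trace")
    n_eval = trace.iterations * trace.folds
    err = steps["mean_test_error"].to_numpy()
    best = int(np.argmin(err))
    se = steps["sd_test_error"].to_numpy()[best] / np.sqrt(n_eval)
    chosen = int(np.argmax(err <= err[best] + se)) + 1  # first index within 1 SE
    return tuple(steps["feature"].iloc[:chosen])


def fit_logistic_pfs(matrix_train: pd.DataFrame, pfs: tuple[str, ...],
                     seed: int | None = None) -> FittedClassifier:
    """Additive logistic model on a predictive feature set; scores are
    probabilities of the pathogenic class."""
    data = complete_cases(matrix_train, list(pfs))
    x, y = _xy(data, list(pfs))
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    res = _fit_logit(x, y)
    return FittedClassifier("logistic", tuple(pfs), res, seed)
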