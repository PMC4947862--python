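"""Correlation-structure analysis of the numeric features.

Features are clustered hierarchically on the distance 1 - |Pearson r|, so that
strongly positively or negatively correlated features (e.g. the conservation
scores, or polarity and hydropathy amino-acid indices) fall into one cluster.
The number of clusters is chosen by scanning k and maximising the mean
silhouette width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples


@dataclass
class ClusteringResult:
    k: int
    labels: pd.Series              # feature -> cluster id (0..k-1)
    silhouette_widths: pd.Series   # per-feature width in [-1, 1]
    mean_width: float

    @property
    def cluster_means(self) -> pd.Series:
        return self.silhouette_widths.groupby(self.labels).mean()


def abs_corr(matrix: pd.DataFrame, numeric_features: list[str]) -> pd.DataFrame:
    """Pairwise |Pearson r| on pairwise-complete observations.

    Categorical features must be excluded by the caller.  A zero-variance
    feature has no defined correlation and raises, naming the feature.
    """
    if len(numeric_features) < 2:
        raise ValueError("need at least 2 numeric features")
    sub = matrix[list(numeric_features)].astype(float)
    for name in numeric_features:
        v = sub[name].dropna()
        if v.nunique() <= 1:
            raise ValueError(f"feature {name!r} has zero variance")
    corr = sub.corr(method="pearson", min_periods=3).abs()
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _distance(corr: pd.DataFrame) -> np.ndarray:
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    # numerical symmetry for squareform
    return (d + d.T) / 2.0


def cluster_features(corr: pd.DataFrame, k: int) -> pd.Series:
    """Average-linkage agglomerative clustering on 1 - |r|, cut at k clusters."""
    n = len(corr)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    z = linkage(squareform(_distance(corr), checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    return pd.Series(labels, index=corr.index, name="cluster")


def silhouette_mean(dist: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Silhouette widths on a precomputed distance matrix; singletons get 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    widths = silhouette_samples(dist, labels, metric="precomputed")
    return widths, float(np.mean(widths))


def optimal_clustering(corr: pd.DataFrame, k_max: int | None = None) -> ClusteringResult:
    """Scan k = 2..k_max and return the silhouette-maximising clustering.

    Deterministic given the correlation matrix; ties go to the smallest k.
    """
    n = len(corr)
    if k_max is None:
        k_max = n - 1
    if k_max > n - 1:
        raise ValueError(f"k_max={k_max} exceeds n_features - 1 = {n - 1}")
    dist = _distance(corr)
    best: ClusteringResult | None = None
    for k in range(2, k_max + 1):
        labels = cluster_features(corr, k)
        widths, mean = silhouette_mean(dist, labels.to_numpy())
        if best is None or mean > best.mean_width:
            best = ClusteringResult(
                k=k, labels=labels,
                silhouette_widths=pd.Series(widths, index=corr.index),
                mean_width=mean,
            )
    assert best is not None
    return best


def corr_long_format(corr: pd.DataFrame) -> pd.DataFrame:
    """Heat-map-ready long format: feature_a, feature_b, abs_r."""
    long = corr.stack().reset_index()
    long.columns = ["feature_a", "feature_b", "abs_r"]
    return long
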