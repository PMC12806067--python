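"""Clustering of eigen-feature tables and silhouette comparison.

Reproduces the comparison design of the clustering benchmark: K-means,
DBSCAN and four hierarchical linkages (ward, average, complete — the
"maximum" linkage — and single) are run on eigengrid / eigenharmonic /
eigenspectrum weight tables and scored with the silhouette coefficient
(mean over samples of (b - a) / max(a, b); singleton clusters score 0,
DBSCAN noise points are excluded and its score flagged as inflated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

HIERARCHICAL = ("ward", "average", "complete", "single")
METHODS = ("kmeans", "dbscan") + HIERARCHICAL
#: the paper community's name "maximum" linkage = complete linkage
LINKAGE_ALIASES = {"maximum": "complete"}


@dataclass
class ClusterResult:
    method: str
    labels: np.ndarray
    k: int
    silhouette: float
    seed: int = 0
    params: dict = field(default_factory=dict)


def default_eps(X: np.ndarray) -> float:
    """Median 4-NN distance: a standard DBSCAN eps heuristic."""
    n = len(X)
    nn = NearestNeighbors(n_neighbors=min(5, n)).fit(X)
    d, _ = nn.kneighbors(X)
    return float(np.median(d[:, -1]))


def cluster(weights: np.ndarray | pd.DataFrame, method: str,
            k: int | None = None, eps: float | None = None,
            min_samples: int = 5, seed: int = 0) -> ClusterResult:
    """Cluster an (N, K) weight table with the named method.

    Euclidean metric throughout; results are deterministic given the
    seed.  ``k`` is required for K-means and the hierarchical linkages;
    DBSCAN instead takes ``eps`` (defaulting to the median 4-NN
    distance) and labels noise as -1.
    """
    X = np.asarray(weights, dtype=float)
    if X.ndim != 2 or len(X) < 3:
        raise ValueError("need an (N, K) table with N >= 3")
    if not np.all(np.isfinite(X)):
        raise ValueError("weights contain non-finite values")
    method = LINKAGE_ALIASES.get(method, method)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if np.allclose(X, X[0]):
        warnings.warn("all points identical: degenerate partition", stacklevel=2)
    params: dict = {}
    if method == "kmeans":
        if k is None:
            raise ValueError("kmeans requires k")
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        params = {"k": k}
    elif method == "dbscan":
        if eps is None:
            eps = default_eps(X)
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
        params = {"eps": eps, "min_samples": min_samples}
    else:
        if k is None:
            raise ValueError(f"{method} linkage requires k")
        labels = AgglomerativeClustering(n_clusters=k, linkage=method).fit_predict(X)
        params = {"k": k}
    n_clusters = len(set(labels) - {-1})
    try:
        score = silhouette(X, labels)
    except ValueError:
        score = float("nan")
    return ClusterResult(method, np.asarray(labels), n_clusters, score,
                         seed=seed, params=params)


def silhouette(weights: np.ndarray | pd.DataFrame, labels: np.ndarray) -> float:
    """Silhouette coefficient of a partition, noise (-1) excluded.

    Requires at least two non-noise clusters; raises otherwise.
    """
    X = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    mask = labels != -1
    X, labels = X[mask], labels[mask]
    n_labels = len(set(labels))
    if n_labels < 2:
        raise ValueError("silhouette undefined for fewer than 2 clusters")
    if n_labels == len(labels):
        return 0.0  # every cluster is a singleton; each scores 0 by convention
    return float(silhouette_score(X, labels, metric="euclidean"))


def best_k_silhouette(X: np.ndarray, method: str, k_range=range(2, 11),
                      seed: int = 0) -> tuple[float, int]:
    """Max silhouette over a k sweep (the cluster count is not dictated
    by the data model, so each method is given its best k)."""
    best, best_k = -np.inf, None
    for k in k_range:
        if k >= len(X):
            break
        res = cluster(X, method, k=k, seed=seed)
        if np.isfinite(res.silhouette) and res.silhouette > best:
            best, best_k = res.silhouette, k
    if best_k is None:
        return float("nan"), 0
    return best, best_k


def compare_methods(feature_tables: dict[str, np.ndarray | pd.DataFrame],
                    methods: tuple[str, ...] = METHODS,
                    k_range=range(2, 11), seed: int = 0) -> pd.DataFrame:
    """Silhouette score matrix: one row per method, one column per feature kind.

    K-means and hierarchical linkages are swept over ``k_range`` and
    report their best k's silhouette.  DBSCAN rows carry a caveat flag:
    scoring only its retained (non-noise) points inflates the
    coefficient.
    """
    kinds = list(feature_tables)
    rows = []
    for method in methods:
        method = LINKAGE_ALIASES.get(method, method)
        row: dict = {"method": method,
                     "inflated": method == "dbscan"}
        for kind in kinds:
            X = np.asarray(feature_tables[kind], dtype=float)
            if method == "dbscan":
                res = cluster(X, "dbscan", seed=seed)
                row[kind] = res.silhouette
            else:
                score, _ = best_k_silhouette(X, method, k_range, seed)
                row[kind] = score
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
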