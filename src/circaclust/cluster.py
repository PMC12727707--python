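"""Two-step clustering of circadian metrics: PCA reduction + k-means.

The procedure standardises the participant x 36 metric matrix, reduces it
by PCA on the correlation matrix retaining components by the joint rule
(eigenvalue >= 1 and cumulative explained variance >= 75%; the larger of
the two implied counts is kept so both constraints hold), then sweeps
k-means over K = 4..12 with many random restarts and ranks candidate K by
silhouette (primary) and Davies-Bouldin (secondary) among solutions whose
smallest cluster meets a minimum size. The final K remains
user-confirmable — cluster interpretability is a human step — with the
top-ranked eligible K as the automated default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.utils.validation import check_is_fitted

from .metrics import METRIC_NAMES

__all__ = [
    "correlation_matrix",
    "standardize",
    "MetricStandardizer",
    "CircadianPca",
    "ClusterSolution",
    "kmeans_fit",
    "sweep_k",
    "select_k",
    "cluster_profiles",
    "find_medoids",
    "CircadianClusterPipeline",
]


def correlation_matrix(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of the metric matrix,
    ordered by circadian dimension (RAR, daytime, sleep, chronotype)."""
    if len(metrics.dropna(how="any")) < 3:
        raise ValueError("need at least 3 complete rows")
    order = [m for m in METRIC_NAMES if m in metrics.columns]
    extra = [c for c in metrics.columns if c not in order]
    ordered = metrics[order + extra]
    zero_var = ordered.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance metrics produce empty correlations: "
            f"{list(ordered.columns[zero_var])}"
        )
    return ordered.corr(method="pearson")


def standardize(metrics: pd.DataFrame):
    """Column-wise z-scores with the sample SD (ddof=1, as R's scale).

    Returns (z-matrix, means, sds); raises on zero-SD columns.
    """
    means = metrics.mean()
    sds = metrics.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(
            f"zero-SD columns cannot be standardised: {list(metrics.columns[sds == 0])}"
        )
    return (metrics - means) / sds, means, sds


class MetricStandardizer(BaseEstimator, TransformerMixin):
    """Stores the training means/SDs so new participants can be projected."""

    def fit(self, X: pd.DataFrame, y=None) -> "MetricStandardizer":
        _, self.means_, self.sds_ = standardize(X)
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "means_")
        return (X - self.means_) / self.sds_


class CircadianPca(BaseEstimator, TransformerMixin):
    """PCA on the correlation matrix with the joint retention rule.

    Retains ``n = max(#{eigenvalue >= eigen_min}, smallest m with
    cumulative variance >= cumvar_min)`` components; both candidate
    counts are kept on the fitted object. Null components (eigenvalue
    below ``null_tol``) are never retained.
    """

    def __init__(self, eigen_min: float = 1.0, cumvar_min: float = 0.75,
                 null_tol: float = 1e-10):
        self.eigen_min = eigen_min
        self.cumvar_min = cumvar_min
        self.null_tol = null_tol

    def fit(self, Z: pd.DataFrame, y=None) -> "CircadianPca":
        Zv = np.asarray(Z, float)
        if np.isnan(Zv).any():
            raise ValueError("PCA input must be complete (drop missing rows upstream)")
        n, p = Zv.shape
        if n <= p:
            warnings.warn("fewer observations than metrics: PCA is rank deficient")
        corr = np.corrcoef(Zv, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.maximum(eigvals[order], 0.0)
        eigvecs = eigvecs[:, order]
        # deterministic sign: largest-|loading| entry positive
        flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(p)])
        flip[flip == 0] = 1.0
        eigvecs = eigvecs * flip
        cumvar = np.cumsum(eigvals) / eigvals.sum()
        n_eigen = int(np.sum(eigvals >= self.eigen_min))
        n_cumvar = int(np.searchsorted(cumvar, self.cumvar_min - 1e-12) + 1)
        n_nonnull = int(np.sum(eigvals > self.null_tol))
        n_keep = min(max(n_eigen, n_cumvar), n_nonnull)
        self.eigenvalues_ = eigvals
        self.loadings_ = pd.DataFrame(
            eigvecs, index=Z.columns if hasattr(Z, "columns") else None,
            columns=[f"PC{i+1}" for i in range(p)],
        )
        self.n_retained_ = max(n_keep, 1)
        self.n_eigen_rule_ = n_eigen
        self.n_cumvar_rule_ = n_cumvar
        self.cumvar_ = float(cumvar[self.n_retained_ - 1])
        return self

    def transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        Zv = np.asarray(Z, float)
        scores = Zv @ self.loadings_.values[:, : self.n_retained_]
        index = Z.index if hasattr(Z, "index") else None
        return pd.DataFrame(scores, index=index,
                            columns=[f"PC{i+1}" for i in range(self.n_retained_)])

    def fit_transform(self, Z: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(Z).transform(Z)


@dataclass
class ClusterSolution:
    """One fitted k-means solution on the component scores."""

    K: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    silhouette: float
    davies_bouldin: float
    sizes: np.ndarray
    medoid_idx: np.ndarray = field(default=None)


def _criteria(scores: np.ndarray, labels: np.ndarray, seed: int,
              silhouette_cap: int = 20000):
    n_labels = len(np.unique(labels))
    if n_labels < 2 or n_labels >= scores.shape[0]:
        return np.nan, np.nan
    sample = silhouette_cap if scores.shape[0] > silhouette_cap else None
    sil = silhouette_score(scores, labels, sample_size=sample,
                           random_state=seed if sample else None)
    return float(sil), float(davies_bouldin_score(scores, labels))


def kmeans_fit(
    scores,
    K: int,
    n_start: int = 5000,
    max_iter: int = 10000,
    seed: int = 0,
) -> ClusterSolution:
    """k-means with many k-means++ restarts; best inertia kept."""
    X = np.asarray(scores, float)
    if K >= X.shape[0] + 1:
        raise ValueError("K must not exceed the number of observations")
    km = KMeans(n_clusters=K, n_init=n_start, max_iter=max_iter,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    sil, db = _criteria(X, labels, seed)
    sizes = np.bincount(labels, minlength=K)
    sol = ClusterSolution(
        K=K, assignments=labels, centroids=km.cluster_centers_,
        inertia=float(km.inertia_), silhouette=sil, davies_bouldin=db,
        sizes=sizes,
    )
    sol.medoid_idx = find_medoids(X, labels, km.cluster_centers_)
    return sol


def sweep_k(
    scores,
    k_min: int = 4,
    k_max: int = 12,
    n_start: int = 5000,
    max_iter: int = 10000,
    seed: int = 0,
) -> Dict[int, ClusterSolution]:
    """Fit k-means for every K in [k_min, k_max]."""
    return {
        K: kmeans_fit(scores, K, n_start=n_start, max_iter=max_iter, seed=seed)
        for K in range(k_min, k_max + 1)
    }


def select_k(solutions: Dict[int, ClusterSolution], min_size: int = 200) -> pd.DataFrame:
    """Criteria-by-K table with eligibility and ranking.

    Solutions whose smallest cluster falls below ``min_size`` are flagged
    ineligible; eligible K are ranked by silhouette (descending) then
    Davies-Bouldin (ascending). The top-ranked eligible K is marked
    ``recommended``; when none is eligible the recommendation is empty.
    """
    rows = []
    for K, sol in sorted(solutions.items()):
        rows.append(
            {
                "K": K,
                "inertia": sol.inertia,
                "silhouette": sol.silhouette,
                "davies_bouldin": sol.davies_bouldin,
                "min_cluster_size": int(sol.sizes.min()),
                "eligible": bool(sol.sizes.min() >= min_size),
            }
        )
    table = pd.DataFrame(rows).set_index("K")
    table["recommended"] = False
    eligible = table[table["eligible"]]
    if len(eligible):
        best = eligible.sort_values(
            ["silhouette", "davies_bouldin"], ascending=[False, True]
        ).index[0]
        table.loc[best, "recommended"] = True
    return table


def find_medoids(scores, assignments, centroids=None) -> np.ndarray:
    """Medoid (row index of the most central participant) per cluster.

    The medoid minimises the Euclidean distance to its own cluster
    centroid in score space; ties resolve to the lowest row index.
    """
    X = np.asarray(scores, float)
    labels = np.asarray(assignments)
    ks = np.unique(labels)
    if centroids is None:
        centroids = np.vstack([X[labels == k].mean(axis=0) for k in ks])
    medoids = np.empty(len(ks), dtype=int)
    for j, k in enumerate(ks):
        idx = np.flatnonzero(labels == k)
        d = np.linalg.norm(X[idx] - centroids[j], axis=1)
        medoids[j] = idx[np.argmin(d)]
    return medoids


def cluster_profiles(
    z: pd.DataFrame, raw: pd.DataFrame, assignments
) -> Dict[str, pd.DataFrame]:
    """Per-cluster metric profiles.

    Returns standardized means (clusters x metrics), raw means, raw SDs,
    and a long-format table of metrics ranked by |z-mean| within each
    cluster.
    """
    labels = pd.Series(np.asarray(assignments), index=z.index, name="cluster")
    z_mean = z.groupby(labels).mean()
    raw_mean = raw.groupby(labels).mean()
    raw_sd = raw.groupby(labels).std(ddof=1)
    ranked = (
        z_mean.stack()
        .rename("z_mean")
        .reset_index()
        .rename(columns={"level_1": "metric"})
    )
    ranked["abs_z"] = ranked["z_mean"].abs()
    ranked = ranked.sort_values(["cluster", "abs_z"], ascending=[True, False])
    ranked["rank"] = ranked.groupby("cluster").cumcount() + 1
    return {
        "z_mean": z_mean,
        "raw_mean": raw_mean,
        "raw_sd": raw_sd,
        "ranked": ranked.reset_index(drop=True),
    }


class CircadianClusterPipeline(BaseEstimator):
    """standardise -> PCA -> k-means sweep -> criterion-based K selection.

    Parameters
    ----------
    k_min, k_max : int
        Range of cluster counts swept (default 4..12).
    n_start, max_iter : int
        k-means restarts and iteration cap per restart.
    eigen_min, cumvar_min : float
        Component retention rule for the PCA step.
    min_size : int
        Minimum admissible cluster size for an eligible K.
    k : int, optional
        Human-confirmed override of the automated K recommendation.
    random_state : int
        Seed controlling k-means restarts (and silhouette subsampling).

    Fitted attributes include ``scaler_``, ``pca_``, ``scores_``,
    ``solutions_``, ``selection_``, ``k_``, ``labels_``, ``profiles_``
    and ``medoid_ids_``. Rows with any missing metric are excluded from
    clustering (complete-case) and keep label -1 in ``labels_``.
    """

    def __init__(self, k_min: int = 4, k_max: int = 12, n_start: int = 5000,
                 max_iter: int = 10000, eigen_min: float = 1.0,
                 cumvar_min: float = 0.75, min_size: int = 200,
                 k: Optional[int] = None, random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.n_start = n_start
        self.max_iter = max_iter
        self.eigen_min = eigen_min
        self.cumvar_min = cumvar_min
        self.min_size = min_size
        self.k = k
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "CircadianClusterPipeline":
        complete = X.dropna(how="any")
        self.n_dropped_ = len(X) - len(complete)
        self.scaler_ = MetricStandardizer().fit(complete)
        Z = self.scaler_.transform(complete)
        self.pca_ = CircadianPca(self.eigen_min, self.cumvar_min).fit(Z)
        self.scores_ = self.pca_.transform(Z)
        self.solutions_ = sweep_k(
            self.scores_, self.k_min, self.k_max,
            n_start=self.n_start, max_iter=self.max_iter, seed=self.random_state,
        )
        self.selection_ = select_k(self.solutions_, self.min_size)
        if self.k is not None:
            self.k_ = int(self.k)
        else:
            rec = self.selection_.index[self.selection_["recommended"]]
            self.k_ = int(rec[0]) if len(rec) else None
        if self.k_ is None:
            warnings.warn("no eligible K: inspect selection_ and set k explicitly")
            self.labels_ = pd.Series(-1, index=X.index, name="cluster")
            return self
        self.solution_ = self.solutions_[self.k_]
        labels = pd.Series(-1, index=X.index, name="cluster", dtype=int)
        labels.loc[complete.index] = self.solution_.assignments
        self.labels_ = labels
        self.profiles_ = cluster_profiles(Z, complete, self.solution_.assignments)
        self.medoid_ids_ = [
            complete.index[i] for i in self.solution_.medoid_idx
        ]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Assign new participants to the nearest fitted centroid."""
        check_is_fitted(self, "solution_")
        Z = self.scaler_.transform(X[self.scaler_.feature_names_in_])
        scores = self.pca_.transform(Z)
        d = np.linalg.norm(
            scores.values[:, None, :] - self.solution_.centroids[None, :, :], axis=2
        )
        return d.argmin(axis=1)

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_
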