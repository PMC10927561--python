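"""Trajectory typology: clustering sites by their temporal trends.

Each site is represented by four per-decade trends (total abundance,
species richness, Simpson dissimilarity, turnover; the two non-native
shares are excluded for their heavy-tailed trend distributions).  A
standardized-variable PCA summarizes the covariation among trends, and a
trimmed k-means (k = 6 clusters, 5% of the most outlying sites trimmed)
partitions sites into trajectory types.  Sites whose second-best cluster
lies within 1.5x the distance of their best cluster are ambiguous and
left unassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kurtosis
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

TREND_VARIABLES = ("total_abundance", "richness_cov", "simpson_dissim", "turnover")

#: label used for trimmed observations
TRIMMED = -1
#: label used for observations failing the affiliation filter
UNASSIGNED = -2


def trend_matrix(
    site_trends: dict[str, pd.DataFrame],
    variables: tuple[str, ...] = TREND_VARIABLES,
) -> pd.DataFrame:
    """Assemble the site x metric trend matrix from per-response tables.

    ``site_trends`` maps response name -> the table returned by
    ``HierarchicalTrendModel.site_trends`` (with a ``trend_per_decade``
    column).  Sites missing any trend are dropped; column kurtosis is
    attached in ``.attrs`` for the heavy-tail report.
    """
    pieces = []
    for var in variables:
        t = site_trends[var][["site_id", "trend_per_decade"]].rename(
            columns={"trend_per_decade": var}
        )
        pieces.append(t.set_index("site_id"))
    mat = pd.concat(pieces, axis=1, join="inner").dropna()
    mat.attrs["kurtosis"] = {
        v: float(kurtosis(mat[v], fisher=False)) for v in variables
    }
    return mat


class TrendPCA(BaseEstimator):
    """PCA of the standardized trend matrix.

    Attributes after ``fit``: ``loadings_`` (orthonormal eigenvectors),
    ``explained_variance_ratio_``, ``scores_``.
    """

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "TrendPCA":
        A = np.asarray(X, dtype=float)
        if A.shape[0] < 5:
            raise ValueError("PCA of site trends needs at least 5 sites")
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            cols = list(X.columns) if hasattr(X, "columns") else list(range(A.shape[1]))
            bad = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"constant trend column(s): {bad}")
        Z = (A - A.mean(axis=0)) / sd
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        eig = s ** 2 / (A.shape[0] - 1)
        self.loadings_ = vt.T
        self.explained_variance_ = eig
        self.explained_variance_ratio_ = eig / eig.sum()
        self.scores_ = Z @ vt.T
        self._mean = A.mean(axis=0)
        self._sd = sd
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        Z = (np.asarray(X, dtype=float) - self._mean) / self._sd
        return Z @ self.loadings_


def trend_pca(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Functional wrapper: (scores, loadings, explained-variance ratios)."""
    est = TrendPCA().fit(X)
    return est.scores_, est.loadings_, est.explained_variance_ratio_


class TrimmedKMeans(BaseEstimator, ClusterMixin):
    """k-means with impartial trimming of the most outlying points.

    Concentration algorithm: assign points to their nearest centre, trim
    the ``ceil(alpha * n)`` points farthest from any centre, recompute
    centres from the untrimmed assignments.  The trimmed within-cluster
    sum of squares never increases; the best of ``n_starts`` random
    initializations (ties: first start) is kept.  Cluster sizes and
    shapes are unconstrained.

    Attributes
    ----------
    cluster_centers_ : ndarray (k, d)
    labels_ : ndarray (n,) — cluster index, or -1 for trimmed points
    inertia_ : float — trimmed within-cluster sum of squares
    """

    def __init__(
        self,
        n_clusters: int = 6,
        alpha: float = 0.05,
        n_starts: int = 50,
        min_iter: int = 100,
        max_iter: int = 125,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.n_starts = n_starts
        self.min_iter = min_iter
        self.max_iter = max_iter
        self.random_state = random_state

    def _one_start(
        self, X: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, np.ndarray, np.ndarray, int] | None:
        n, d = X.shape
        k = self.n_clusters
        n_trim = int(np.ceil(self.alpha * n))
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, TRIMMED)
        obj_prev = np.inf
        n_iter = 0
        for it in range(self.max_iter):
            n_iter = it + 1
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            nearest = d2.argmin(axis=1)
            best = d2[np.arange(n), nearest]
            labels = nearest.copy()
            if n_trim > 0:
                cut = np.argsort(best)[n - n_trim:]
                labels[cut] = TRIMMED
            obj = float(best[labels != TRIMMED].sum())
            for j in range(k):
                pts = X[labels == j]
                if len(pts) == 0:
                    return None  # empty cluster: caller restarts
                centers[j] = pts.mean(axis=0)
            if it + 1 >= self.min_iter and obj >= obj_prev - 1e-12:
                break
            obj_prev = obj
        return obj, centers, labels, n_iter

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "TrimmedKMeans":
        A = np.asarray(X, dtype=float)
        n = A.shape[0]
        if n * (1 - self.alpha) <= self.n_clusters:
            raise ValueError("not enough untrimmed points for the requested k")
        rng = np.random.default_rng(self.random_state)
        best = None
        starts_done = 0
        attempts = 0
        while starts_done < self.n_starts and attempts < 10 * self.n_starts:
            attempts += 1
            result = self._one_start(A, rng)
            if result is None:
                continue  # degenerate start (empty cluster): redraw
            starts_done += 1
            if best is None or result[0] < best[0] - 1e-12:
                best = result
        if best is None:
            raise RuntimeError("all trimmed k-means starts degenerated")
        self.inertia_, self.cluster_centers_, self.labels_, self.n_iter_ = best
        self.n_features_in_ = A.shape[1]
        return self

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        A = np.asarray(X, dtype=float)
        d2 = ((A[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def center_distances(self, X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distances to the best and second-best centre for every point."""
        check_is_fitted(self, "cluster_centers_")
        A = np.asarray(X, dtype=float)
        d = np.sqrt(((A[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2))
        d_sorted = np.sort(d, axis=1)
        return d_sorted[:, 0], d_sorted[:, 1]


def trimmed_kmeans(
    X: pd.DataFrame | np.ndarray,
    n_clusters: int = 6,
    alpha: float = 0.05,
    n_starts: int = 50,
    seed: int | None = None,
    **kwargs,
) -> TrimmedKMeans:
    """Functional wrapper around :class:`TrimmedKMeans`."""
    return TrimmedKMeans(
        n_clusters=n_clusters, alpha=alpha, n_starts=n_starts,
        random_state=seed, **kwargs,
    ).fit(X)


def affiliation_filter(
    est: TrimmedKMeans, X: pd.DataFrame | np.ndarray, threshold: float = 1.5
) -> np.ndarray:
    """Unassign ambiguous sites: those whose second-best centre distance
    is below ``threshold`` times the best one.

    Trimmed points keep their -1 label; ambiguous points get -2.
    """
    d1, d2 = est.center_distances(X)
    labels = est.labels_.copy()
    ambiguous = (labels != TRIMMED) & (d2 < threshold * d1)
    labels[ambiguous] = UNASSIGNED
    return labels


def cluster_frequencies(
    labels: np.ndarray, realms: pd.Series | None = None
) -> pd.DataFrame:
    """Per-cluster share of assigned sites, overall and per realm."""
    lab = np.asarray(labels)
    assigned = lab >= 0
    clusters = np.unique(lab[assigned])
    rows = []
    total = assigned.sum()
    for c in clusters:
        rows.append({"realm": "all", "cluster": int(c),
                     "share": float((lab == c).sum() / total)})
    if realms is not None:
        realms = pd.Series(np.asarray(realms))
        for realm in sorted(realms[assigned].unique()):
            in_realm = assigned & (realms == realm).to_numpy()
            denom = in_realm.sum()
            for c in clusters:
                rows.append({"realm": realm, "cluster": int(c),
                             "share": float((lab[in_realm] == c).sum() / denom)})
    return pd.DataFrame(rows)


def objective_scan(
    X: pd.DataFrame | np.ndarray,
    ks: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    alphas: tuple[float, ...] = (0.0, 0.05, 0.10),
    n_starts: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Diagnostic scan of the trimmed within-cluster SS over (k, alpha).

    A report to eyeball when choosing the partition, not an automatic
    selector: the objective always improves with k and with trimming, so
    the useful signal is where the improvement flattens.
    """
    rows = []
    for alpha in alphas:
        for k in ks:
            km = TrimmedKMeans(
                n_clusters=k, alpha=alpha, n_starts=n_starts,
                min_iter=10, random_state=seed,
            ).fit(X)
            rows.append({"k": k, "alpha": alpha, "objective": km.inertia_})
    return pd.DataFrame(rows)


def name_clusters(centers: np.ndarray, variables: tuple[str, ...] = TREND_VARIABLES) -> list[str]:
    """Post-hoc descriptive labels comparing each centre to the overall
    centre spread — labels only, no semantics."""
    centers = np.asarray(centers, dtype=float)
    med = np.median(centers, axis=0)
    spread = centers.std(axis=0, ddof=1) if len(centers) > 1 else np.ones(centers.shape[1])
    spread[spread == 0] = 1.0
    names = []
    for c in centers:
        z = (c - med) / spread
        j = int(np.argmax(np.abs(z)))
        if abs(z[j]) < 0.5:
            names.append("medium change")
        else:
            direction = "increase" if z[j] > 0 else "decrease"
            names.append(f"{direction} in {variables[j]}")
    return names
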