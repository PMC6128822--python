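"""Hotspot topography: k-means++ clustering with silhouette model selection.

The clustering mirrors the classic two-phase k-means: distance-squared
weighted (k-means++) seeding, batch Lloyd iterations to convergence, then an
online phase that moves one point at a time whenever the move lowers the
within-cluster sum of squares (WCSS). The whole procedure is restarted many
times (1000 by default) with fresh random seeds and the restart with minimal
WCSS wins. The number of clusters is chosen by scanning k and maximizing the
mean silhouette.

Distances are plain Euclidean millimeters on MNI coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .hotspots import HotspotSet

__all__ = [
    "KMeansTopography",
    "SilhouetteKSelector",
    "KMeansSolution",
    "ContingencyResult",
    "kmeanspp_seed",
    "kmeans_fit",
    "silhouette_scores",
    "select_k",
    "cross_tab",
]

#: mean-silhouette floor below which a selected solution is flagged as weak
WEAK_STRUCTURE_SILHOUETTE = 0.25


# ---------------------------------------------------------------------------
# seeding and the two-phase single fit


def kmeanspp_seed(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ initial centroids: first uniform, then D^2-weighted draws."""
    X = np.asarray(points, dtype=float)
    n = len(X)
    if k > len(np.unique(X, axis=0)):
        raise ValueError("k exceeds the number of distinct points")
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a chosen centroid
            probs = np.full(n, 1.0 / n)
        else:
            probs = d2 / total
        centroids[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = cdist(X, centroids, "sqeuclidean")
    labels = d2.argmin(axis=1)
    return labels, d2


def _wcss(d2: np.ndarray, labels: np.ndarray) -> float:
    return float(d2[np.arange(len(labels)), labels].sum())


def _repair_empty(X, centroids, labels, d2):
    """Give any empty cluster the point currently farthest from its centroid."""
    k = len(centroids)
    for j in range(k):
        if not np.any(labels == j):
            worst = int(d2[np.arange(len(labels)), labels].argmax())
            labels[worst] = j
            centroids[j] = X[worst]
    return centroids, labels


def _batch_phase(X, centroids, tol: float, max_iter: int):
    labels, d2 = _assign(X, centroids)
    centroids, labels = _repair_empty(X, centroids, labels, d2)
    prev = np.inf
    for _ in range(max_iter):
        for j in range(len(centroids)):
            members = X[labels == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
        new_labels, d2 = _assign(X, centroids)
        centroids, new_labels = _repair_empty(X, centroids, new_labels, d2)
        cur = _wcss(d2, new_labels)
        if cur > prev + 1e-8:
            raise AssertionError("WCSS increased during batch phase")
        changed = np.any(new_labels != labels)
        labels = new_labels
        if not changed or prev - cur < tol:
            prev = cur
            break
        prev = cur
    return centroids, labels, prev


def _online_phase(X, centroids, labels, wcss: float, max_moves: int):
    """Single-point moves: apply the best WCSS-lowering reassignment until none
    helps (capped). Centroids update incrementally after each move."""
    k = len(centroids)
    counts = np.bincount(labels, minlength=k).astype(float)
    for _ in range(max_moves):
        d2 = cdist(X, centroids, "sqeuclidean")
        own = d2[np.arange(len(labels)), labels]
        # removal gain n_a/(n_a-1) * d(i, c_a)^2 ; singletons may not move
        na = counts[labels]
        removable = na > 1
        gain = np.where(removable, na / np.maximum(na - 1, 1) * own, -np.inf)
        # insertion cost n_b/(n_b+1) * d(i, c_b)^2
        cost = counts / (counts + 1) * d2
        cost[np.arange(len(labels)), labels] = np.inf
        best_b = cost.argmin(axis=1)
        delta = cost[np.arange(len(labels)), best_b] - gain
        i = int(delta.argmin())
        if not np.isfinite(delta[i]) or delta[i] >= -1e-12:
            break
        a, b = labels[i], int(best_b[i])
        centroids[a] = (centroids[a] * counts[a] - X[i]) / (counts[a] - 1)
        centroids[b] = (centroids[b] * counts[b] + X[i]) / (counts[b] + 1)
        counts[a] -= 1
        counts[b] += 1
        labels[i] = b
        new_wcss = wcss + float(delta[i])
        if new_wcss > wcss + 1e-8:
            raise AssertionError("WCSS increased during online phase")
        wcss = new_wcss
    # final exact recompute to avoid drift from incremental updates
    labels, d2 = _assign(X, centroids)
    for j in range(k):
        members = X[labels == j]
        if len(members):
            centroids[j] = members.mean(axis=0)
    labels, d2 = _assign(X, centroids)
    return centroids, labels, _wcss(d2, labels)


@dataclass
class KMeansSolution:
    """A fitted clustering of hotspot coordinates."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    wcss: float
    silhouettes: np.ndarray
    mean_silhouette: float
    n_restarts: int
    seed: int | None
    best_restart_index: int = 0

    def cluster_shares(self) -> np.ndarray:
        """Fraction of points per cluster (index-aligned with centroids)."""
        return np.bincount(self.assignments, minlength=self.k) / len(self.assignments)


class KMeansTopography(ClusterMixin, BaseEstimator):
    """Two-phase (batch + online) k-means with k-means++ restarts.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    n_restarts : int, default 1000
        Independent k-means++ seedings; the minimal-WCSS restart is returned
        (ties go to the lowest restart index).
    tol : float, default 1e-10
        Batch-phase WCSS improvement (mm^2) below which iteration stops.
    max_batch_iter, max_online_moves : int
        Iteration caps for the two phases.
    random_state : int or None
        Seed for all restarts; no hidden global state.

    Attributes
    ----------
    cluster_centers_ : (k, 3) ndarray of MNI mm
    labels_ : (n,) ndarray of cluster indices
    inertia_ : float, the within-cluster sum of squared mm distances
    best_restart_ : index of the winning restart
    """

    def __init__(self, n_clusters: int = 3, n_restarts: int = 1000, tol: float = 1e-10,
                 max_batch_iter: int = 100, max_online_moves: int = 100,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_batch_iter = max_batch_iter
        self.max_online_moves = max_online_moves
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_points, n_dims)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if len(np.unique(X, axis=0)) < self.n_clusters:
            raise ValueError("fewer distinct points than clusters")
        rng = np.random.default_rng(self.random_state)
        best = None
        for r in range(self.n_restarts):
            centroids = kmeanspp_seed(X, self.n_clusters, rng)
            centroids, labels, wcss = _batch_phase(X, centroids.copy(), self.tol,
                                                   self.max_batch_iter)
            centroids, labels, wcss = _online_phase(X, centroids, labels, wcss,
                                                    self.max_online_moves)
            if best is None or wcss < best[0] - 1e-12:
                best = (wcss, centroids, labels, r)
        wcss, centroids, labels, r = best
        self.cluster_centers_ = centroids
        self.labels_ = labels
        self.inertia_ = float(wcss)
        self.best_restart_ = int(r)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return _assign(X, self.cluster_centers_)[0]


def kmeans_fit(points, k: int, n_restarts: int = 1000,
               rng: int | np.random.Generator | None = None) -> KMeansSolution:
    """Fit the two-phase k-means and return a :class:`KMeansSolution` with
    silhouettes attached (silhouettes are NaN for k=1)."""
    seed = rng
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31 - 1))
    est = KMeansTopography(n_clusters=k, n_restarts=n_restarts, random_state=seed)
    points = np.asarray(points, dtype=float)
    est.fit(points)
    if k >= 2:
        sil, mean_sil = silhouette_scores(points, est.labels_)
    else:
        sil, mean_sil = np.full(len(points), np.nan), np.nan
    return KMeansSolution(k=k, centroids=est.cluster_centers_, assignments=est.labels_,
                          wcss=est.inertia_, silhouettes=sil, mean_silhouette=mean_sil,
                          n_restarts=n_restarts, seed=seed if isinstance(seed, int) else None,
                          best_restart_index=est.best_restart_)


# ---------------------------------------------------------------------------
# silhouettes and model selection


def silhouette_scores(points, assignments) -> tuple[np.ndarray, float]:
    """Per-point silhouettes ``s = (b - a) / max(a, b)`` and their mean.

    ``a`` is the mean distance to other members of the point's cluster, ``b``
    the smallest mean distance to any other cluster. Singleton clusters (and
    the degenerate case a = b = 0) score 0 by convention.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouettes need >= 2 clusters")
    D = cdist(X, X)
    n = len(X)
    s = np.zeros(n)
    mean_to = np.empty((n, len(uniq)))
    counts = np.empty(len(uniq))
    for j, lab in enumerate(uniq):
        members = labels == lab
        counts[j] = members.sum()
        mean_to[:, j] = D[:, members].sum(axis=1)
    for i in range(n):
        j_own = int(np.where(uniq == labels[i])[0][0])
        if counts[j_own] == 1:
            s[i] = 0.0
            continue
        a = mean_to[i, j_own] / (counts[j_own] - 1)
        others = [mean_to[i, j] / counts[j] for j in range(len(uniq)) if j != j_own]
        b = min(others)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


class SilhouetteKSelector(ClusterMixin, BaseEstimator):
    """Scan k, fit the two-phase k-means at each, select by mean silhouette.

    Ties go to the smaller k. A winning mean silhouette below
    ``weak_threshold`` flags the solution as weak structure rather than
    failing.

    Attributes
    ----------
    n_clusters_ : selected k
    best_solution_ : KMeansSolution for the selected k
    diagnostics_ : DataFrame with one row per k (k, wcss, mean_silhouette)
    weak_structure_ : bool
    labels_, cluster_centers_ : from the selected solution
    """

    def __init__(self, k_min: int = 2, k_max: int = 10, n_restarts: int = 1000,
                 random_state: int | None = None,
                 weak_threshold: float = WEAK_STRUCTURE_SILHOUETTE):
        self.k_min = k_min
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.weak_threshold = weak_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.k_max < self.k_min:
            raise ValueError("empty k range")
        n_distinct = len(np.unique(X, axis=0))
        if self.k_max > n_distinct:
            raise ValueError("k_max exceeds the number of distinct points")
        ss = np.random.SeedSequence(self.random_state)
        child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                       for s in ss.spawn(self.k_max - self.k_min + 1)]
        rows = []
        solutions: dict[int, KMeansSolution] = {}
        for k, seed in zip(range(self.k_min, self.k_max + 1), child_seeds):
            sol = kmeans_fit(X, k, n_restarts=self.n_restarts, rng=seed)
            solutions[k] = sol
            rows.append({"k": k, "wcss": sol.wcss, "mean_silhouette": sol.mean_silhouette})
        diag = pd.DataFrame(rows)
        best_k = int(diag.loc[diag["mean_silhouette"].idxmax(), "k"])  # idxmax -> first max (smallest k)
        self.n_clusters_ = best_k
        self.best_solution_ = solutions[best_k]
        self.diagnostics_ = diag
        self.weak_structure_ = bool(self.best_solution_.mean_silhouette < self.weak_threshold)
        self.labels_ = self.best_solution_.assignments
        self.cluster_centers_ = self.best_solution_.centroids
        return self


def select_k(points, k_min: int = 2, k_max: int = 10, n_restarts: int = 1000,
             seed: int | None = None) -> tuple[KMeansSolution, pd.DataFrame]:
    """Fit every k in range and return (best solution, per-k diagnostics)."""
    sel = SilhouetteKSelector(k_min=k_min, k_max=k_max, n_restarts=n_restarts,
                              random_state=seed).fit(np.asarray(points, dtype=float))
    diag = sel.diagnostics_.copy()
    diag["selected"] = diag["k"] == sel.n_clusters_
    diag["weak_structure"] = sel.weak_structure_
    return sel.best_solution_, diag


# ---------------------------------------------------------------------------
# post-hoc contingency tests


@dataclass
class ContingencyResult:
    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    low_expected_warning: bool


def cross_tab(hotspot_set: HotspotSet, solution: KMeansSolution,
              factor: str = "group") -> ContingencyResult:
    """Pearson chi-square on factor x cluster counts (factor in {group, sex}).

    Flags a warning when any expected cell count is below 5.
    """
    if factor not in ("group", "sex"):
        raise ValueError("factor must be 'group' or 'sex'")
    values = [getattr(p, factor) for p in hotspot_set.points]
    if any(v is None for v in values):
        raise ValueError(f"factor {factor!r} missing for some points")
    if len(values) != len(solution.assignments):
        raise ValueError("hotspot set and solution sizes differ")
    table = pd.crosstab(pd.Series(values, name=factor),
                        pd.Series(solution.assignments, name="cluster"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (single row or column)")
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ContingencyResult(table=table, chi2=float(chi2), df=int(df), p=float(p),
                             low_expected_warning=bool((expected < 5).any()))
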