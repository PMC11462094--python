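"""K-means phenotype clustering: k-means++ seeding, Lloyd iterations,
silhouette validation, K and feature-subset selection, ordered labels.

The clustering objective is the sum of squared errors (cluster scatter)

    SSE = sum_i sum_{x in C_i} dist(x, c_i)^2

minimised by alternating nearest-centroid assignment and centroid-mean
updates (Lloyd's method). Runs are repeated ``n_init`` times from k-means++
seeds and the lowest-SSE run is kept. Convergence is declared when the
Frobenius norm of the centroid displacement between consecutive iterations
falls below ``tol``.

Cluster quality is scored with silhouette coefficients

    s_x = (b_x - a_x) / max(a_x, b_x)

where a_x is the mean distance from x to the other members of its own
cluster and b_x the mean distance to the members of the nearest other
cluster; points in singleton clusters take s_x = 0 by convention.

Everything here is implemented directly (no clustering library); the test
suite cross-checks against independent oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ActivityWindow, logger

#: Canonical candidate feature names -> ActivityWindow attributes.
FEATURE_ATTRS = {
    "steps": "mean_steps",
    "distance": "mean_distance_miles",
    "mvpa_minutes": "mean_mvpa_minutes",
    "calories": "mean_calories",
    "weekday_days": "weekday_days_used",
    "weekend_days": "weekend_days_used",
}

DEFAULT_FEATURES = ("steps", "distance", "mvpa_minutes")


@dataclass
class KMeansParams:
    k: int = 3
    init: str = "kmeanspp"  # or "random"
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-4
    seed: int | None = 0  # None -> nondeterministic seeding

    def validate(self) -> None:
        if self.k < 1 or self.n_init < 1 or self.max_iter < 1 or self.tol < 0:
            raise ValueError("invalid k-means parameters")
        if self.init not in ("kmeanspp", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class SilhouetteTerms:
    a: np.ndarray  # mean intra-cluster distance per point
    b: np.ndarray  # mean distance to nearest other cluster per point
    s: np.ndarray  # (b - a) / max(a, b), 0 for singletons
    per_cluster_mean: dict[int, float]
    overall_mean: float


@dataclass
class ClusterModel:
    feature_names: tuple[str, ...]
    centroids: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,) cluster indices
    sse: float
    iterations_run: int
    converged: bool
    sse_history: list[float] = field(default_factory=list)
    silhouette: SilhouetteTerms | None = None
    labels: tuple[str, ...] | None = None  # per-cluster ordered labels

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def label_of(self, point_index: int) -> str:
        if self.labels is None:
            raise ValueError("model has no cluster labels; call label_clusters first")
        return self.labels[int(self.assignments[point_index])]

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "centroids": self.centroids.tolist(),
            "sse": self.sse,
            "iterations_run": self.iterations_run,
            "converged": self.converged,
            "labels": list(self.labels) if self.labels else None,
            "average_silhouette": self.silhouette.overall_mean if self.silhouette else None,
            "per_cluster_silhouette": (
                {int(c): v for c, v in self.silhouette.per_cluster_mean.items()} if self.silhouette else None
            ),
            "n_points": int(self.assignments.size),
        }


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or pts.size == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def _sq_dists(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (n, k)."""
    diff = points[:, None, :] - centroids[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def kmeanspp_init(points, k: int, rng: np.random.Generator) -> np.ndarray:
    """D^2 seeding: first centroid uniform; each next centroid sampled with
    probability proportional to the squared distance to the nearest chosen
    centroid, so seeds land generally far apart."""
    pts = _as_points(points)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    centroids = np.empty((k, pts.shape[1]))
    centroids[0] = pts[rng.integers(n)]
    closest = np.sum((pts - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = closest.sum()
        if total == 0:
            # all remaining mass at distance zero: pick uniformly
            centroids[j] = pts[rng.integers(n)]
            continue
        centroids[j] = pts[rng.choice(n, p=closest / total)]
        closest = np.minimum(closest, np.sum((pts - centroids[j]) ** 2, axis=1))
    return centroids


def _single_run(
    pts: np.ndarray, k: int, params: KMeansParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = pts.shape[0]
    if params.init == "kmeanspp":
        centroids = kmeanspp_init(pts, k, rng)
    else:
        centroids = pts[rng.choice(n, size=k, replace=False)].copy()
    assignments = np.zeros(n, dtype=int)
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        d2 = _sq_dists(pts, centroids)
        assignments = np.argmin(d2, axis=1)  # ties -> lowest cluster index
        # repair empty clusters: reseed at the point farthest from its centroid
        for empty in range(k):
            if not np.any(assignments == empty):
                own_d2 = d2[np.arange(n), assignments]
                far = int(np.argmax(own_d2))
                centroids[empty] = pts[far]
                d2 = _sq_dists(pts, centroids)
                assignments = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(n), assignments].sum()))
        new_centroids = np.stack([pts[assignments == j].mean(axis=0) for j in range(k)])
        shift = float(np.linalg.norm(new_centroids - centroids))
        centroids = new_centroids
        if shift < params.tol:
            converged = True
            break
    d2 = _sq_dists(pts, centroids)
    assignments = np.argmin(d2, axis=1)
    sse = float(d2[np.arange(n), assignments].sum())
    history.append(sse)
    return centroids, assignments, sse, iterations, converged, history


def lloyd(
    points,
    params: KMeansParams | None = None,
    feature_names: Sequence[str] | None = None,
    initial_centroids: np.ndarray | None = None,
) -> ClusterModel:
    """Best-of-``n_init`` Lloyd's k-means on raw feature values.

    ``initial_centroids``, when given, is evaluated as one extra candidate
    run (used for warm-started elbow scans). The winning run is the one
    with the lowest SSE.
    """
    params = params or KMeansParams()
    params.validate()
    pts = _as_points(points)
    n = pts.shape[0]
    if params.k > n:
        raise ValueError(f"k={params.k} exceeds n={n}")
    rng = np.random.default_rng(params.seed)
    best: tuple | None = None
    runs = [None] * params.n_init
    if initial_centroids is not None:
        runs = [np.asarray(initial_centroids, dtype=float)] + runs
    for start in runs:
        if start is None:
            result = _single_run(pts, params.k, params, rng)
        else:
            sub = KMeansParams(**{**params.__dict__, "init": "kmeanspp"})
            result = _run_from(pts, start, sub)
        if best is None or result[2] < best[2]:
            best = result
    centroids, assignments, sse, iterations, converged, history = best
    names = tuple(feature_names) if feature_names else tuple(f"f{i}" for i in range(pts.shape[1]))
    return ClusterModel(
        feature_names=names,
        centroids=centroids,
        assignments=assignments,
        sse=sse,
        iterations_run=iterations,
        converged=converged,
        sse_history=history,
    )


def _run_from(pts: np.ndarray, centroids: np.ndarray, params: KMeansParams):
    """Lloyd iterations from explicit starting centroids."""
    n, k = pts.shape[0], centroids.shape[0]
    centroids = centroids.copy()
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        d2 = _sq_dists(pts, centroids)
        assignments = np.argmin(d2, axis=1)
        for empty in range(k):
            if not np.any(assignments == empty):
                own_d2 = d2[np.arange(n), assignments]
                centroids[empty] = pts[int(np.argmax(own_d2))]
                d2 = _sq_dists(pts, centroids)
                assignments = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(n), assignments].sum()))
        new_centroids = np.stack([pts[assignments == j].mean(axis=0) for j in range(k)])
        shift = float(np.linalg.norm(new_centroids - centroids))
        centroids = new_centroids
        if shift < params.tol:
            converged = True
            break
    d2 = _sq_dists(pts, centroids)
    assignments = np.argmin(d2, axis=1)
    sse = float(d2[np.arange(n), assignments].sum())
    history.append(sse)
    return centroids, assignments, sse, iterations, converged, history


def silhouette(points, assignments) -> SilhouetteTerms:
    """Silhouette terms for every point plus per-cluster and overall means.

    a_x excludes the point itself; b_x is the minimum over other clusters of
    the mean distance to that cluster's points; singleton clusters score 0.
    Raises if fewer than two clusters are populated.
    """
    pts = _as_points(points)
    labels = np.asarray(assignments, dtype=int)
    if labels.shape[0] != pts.shape[0]:
        raise ValueError("assignments length must match number of points")
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least 2 non-empty clusters")
    n = pts.shape[0]
    dists = np.sqrt(np.maximum(_sq_dists(pts, pts), 0.0))
    a = np.zeros(n)
    b = np.full(n, np.inf)
    sizes = {int(c): int(np.sum(labels == c)) for c in clusters}
    for c in clusters:
        mask = labels == c
        sums_to_c = dists[:, mask].sum(axis=1)
        size = sizes[int(c)]
        a[mask] = sums_to_c[mask] / max(size - 1, 1)
        other = ~mask
        if size > 0:
            b[other] = np.minimum(b[other], sums_to_c[other] / size)
    s = np.zeros(n)
    nontrivial = np.array([sizes[int(c)] > 1 for c in labels])
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore"):
        s[nontrivial] = (b[nontrivial] - a[nontrivial]) / denom[nontrivial]
    s = np.nan_to_num(s, nan=0.0)
    per_cluster = {int(c): float(s[labels == c].mean()) for c in clusters}
    return SilhouetteTerms(a=a, b=b, s=s, per_cluster_mean=per_cluster, overall_mean=float(s.mean()))


def attach_silhouette(model: ClusterModel, points) -> ClusterModel:
    model.silhouette = silhouette(points, model.assignments)
    return model


def sse_scan(
    points,
    k_range: Sequence[int],
    params: KMeansParams | None = None,
    warm_start: bool = False,
) -> dict[int, float]:
    """Best-of-``n_init`` SSE per K, for elbow inspection.

    With ``warm_start`` each K additionally tries the previous K's solution
    plus one extra centroid at the point farthest from its own centroid,
    which makes the curve provably non-increasing in K.
    """
    params = params or KMeansParams()
    pts = _as_points(points)
    out: dict[int, float] = {}
    prev: ClusterModel | None = None
    for k in sorted(set(int(k) for k in k_range)):
        sub = KMeansParams(**{**params.__dict__, "k": k})
        start = None
        if warm_start and prev is not None and prev.k == k - 1:
            d2 = _sq_dists(pts, prev.centroids)
            own = d2[np.arange(pts.shape[0]), prev.assignments]
            start = np.vstack([prev.centroids, pts[int(np.argmax(own))]])
        model = lloyd(pts, sub, initial_centroids=start)
        out[k] = model.sse
        prev = model
    return out


def select_k(
    points,
    k_min: int = 2,
    k_max: int = 5,
    params: KMeansParams | None = None,
) -> tuple[int, dict[int, float]]:
    """Fit each K in [k_min, k_max]; return the K with the highest average
    silhouette (ties to the smaller K) plus the per-K silhouettes."""
    params = params or KMeansParams()
    pts = _as_points(points)
    if k_min < 2 or k_min > k_max:
        raise ValueError("need 2 <= k_min <= k_max (silhouette is undefined for k=1)")
    if pts.shape[0] <= k_max:
        raise ValueError("need more points than k_max")
    scores: dict[int, float] = {}
    for k in range(int(k_min), int(k_max) + 1):
        sub = KMeansParams(**{**params.__dict__, "k": k})
        model = lloyd(pts, sub)
        scores[k] = silhouette(pts, model.assignments).overall_mean
    best_k = max(sorted(scores), key=lambda k: (scores[k], -k))
    return best_k, scores


def scale_features(matrix: np.ndarray, method: str = "none") -> np.ndarray:
    """Optional feature scaling (off by default; raw values cluster well for
    these data and scaling has little effect on cluster quality)."""
    if method == "none":
        return matrix
    if method == "zscore":
        sd = matrix.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (matrix - matrix.mean(axis=0)) / sd
    if method == "minmax":
        lo, hi = matrix.min(axis=0), matrix.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (matrix - lo) / span
    raise ValueError(f"unknown scaling method {method!r}")


def windows_matrix(windows: Sequence[ActivityWindow], features: Sequence[str]) -> np.ndarray:
    """Feature matrix from activity windows; windows with any missing
    selected feature are rejected (callers should filter first)."""
    cols = []
    for f in features:
        attr = FEATURE_ATTRS[f]
        col = np.array([getattr(w, attr) for w in windows], dtype=float)
        cols.append(col)
    matrix = np.column_stack(cols)
    if np.isnan(matrix).any():
        raise ValueError("windows with missing feature values; drop them before clustering")
    return matrix


def feature_subset_search(
    windows: Sequence[ActivityWindow],
    candidate_features: Sequence[str] = tuple(FEATURE_ATTRS),
    params: KMeansParams | None = None,
    min_size: int = 2,
    scaling: str = "none",
) -> tuple[tuple[str, ...], dict[tuple[str, ...], float]]:
    """Exhaustive search over feature subsets (size >= ``min_size``) for the
    combination with the highest average silhouette on raw values."""
    params = params or KMeansParams()
    candidates = tuple(candidate_features)
    if not candidates:
        raise ValueError("candidate feature set is empty")
    unknown = [f for f in candidates if f not in FEATURE_ATTRS]
    if unknown:
        raise ValueError(f"unknown candidate features: {unknown}")
    ranking: dict[tuple[str, ...], float] = {}
    complete = [
        w
        for w in windows
        if all(getattr(w, FEATURE_ATTRS[f]) is not None for f in candidates)
    ]
    if len(complete) < len(windows):
        logger.warning("feature search dropped %d windows with missing features", len(windows) - len(complete))
    for size in range(min_size, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            matrix = scale_features(windows_matrix(complete, subset), scaling)
            model = lloyd(matrix, params, feature_names=subset)
            ranking[subset] = silhouette(matrix, model.assignments).overall_mean
    best = max(sorted(ranking), key=lambda sub: (ranking[sub], -len(sub)))
    return best, ranking


ACTIVITY_LABELS_3 = ("low", "moderate", "high")


def label_clusters(model: ClusterModel) -> ClusterModel:
    """Assign interpretable activity labels ordered by centroid steps.

    With k=3 the clusters become low/moderate/high physical activity by
    ascending centroid mean steps; any other k falls back to generic
    ``level_1..level_k`` labels in the same order.
    """
    order_feature = "steps" if "steps" in model.feature_names else model.feature_names[0]
    col = model.feature_names.index(order_feature)
    order = np.argsort(model.centroids[:, col], kind="stable")
    labels = [""] * model.k
    if model.k == 3:
        names = ACTIVITY_LABELS_3
    else:
        names = tuple(f"level_{i + 1}" for i in range(model.k))
    for rank, cluster_index in enumerate(order):
        labels[int(cluster_index)] = names[rank]
    model.labels = tuple(labels)
    return model
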