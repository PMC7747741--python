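"""Density-based outlier removal over gene vectors.

The neighborhood radius eps is calibrated from the sorted kNN-distance
curve: ranks and distances are each scaled to [0, 1], the finite-difference
derivative of scaled distance with respect to scaled rank is computed, and
the knee is the first rank at which the derivative exceeds a threshold
(default 1, i.e. the local slope first exceeds the curve's average slope).
DBSCAN then partitions the gene vectors into density-reached clusters;
core and border features are retained, noise features are discarded.

DBSCAN point classes follow the classical definitions: a point is *core*
when its eps-neighborhood (closed ball, self included) holds at least
``min_pts`` points; *border* when it is not core but lies within eps of a
core point; *noise* otherwise.  Clusters are the connected components of
core points under eps-reachability, with every border point attached to
the cluster of its lowest-indexed reachable core point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import NoKneeError, ParameterError, ValidationError
from .preprocess import GeneMatrix

NOISE = -1

CORE, BORDER, NOISE_TYPE = "core", "border", "noise"


@dataclass
class KneeResult:
    """Knee-point calibration of the eps radius.

    ``sorted_distances`` are the ascending raw kNN distances,
    ``scaled_distances`` the same scaled to [0, 1]; ``knee_index`` is the
    rank at which the scaled derivative first exceeds
    ``derivative_threshold`` and ``eps`` the distance reported at that
    rank (raw data units by default).
    """

    sorted_distances: np.ndarray
    scaled_distances: np.ndarray
    knee_index: int
    eps: float
    derivative_threshold: float


@dataclass
class DbscanResult:
    """Per-point cluster labels and point types.

    ``labels[i]`` is the cluster id of point ``i`` (0-based, ``-1`` for
    noise); ``point_type[i]`` is ``"core"``, ``"border"`` or ``"noise"``.
    """

    labels: np.ndarray
    point_type: np.ndarray
    eps: float
    min_pts: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0

    def counts(self) -> dict:
        """Per-cluster core/border counts plus the noise total."""
        out = {"noise": int((self.labels == NOISE).sum()), "clusters": []}
        for c in range(self.n_clusters):
            in_c = self.labels == c
            out["clusters"].append({
                "cluster": c,
                "core": int((in_c & (self.point_type == CORE)).sum()),
                "border": int((in_c & (self.point_type == BORDER)).sum()),
            })
        return out


def knn_distance_curve(points: np.ndarray, k: int) -> np.ndarray:
    """Distance of every point to its k-th nearest *other* point, sorted
    ascending (Euclidean metric)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be a 2-D array")
    n = points.shape[0]
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k >= n:
        raise ParameterError(f"k={k} requires at least k+1={k + 1} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    return np.sort(dist[:, k])


#: Fraction of the curve length used as the forward-difference window.
KNEE_WINDOW_FRACTION = 0.05


def estimate_knee(curve, threshold: float = 1.0, eps_scale: str = "raw",
                  window: int | None = None) -> KneeResult:
    """Locate the knee of an ascending kNN-distance curve.

    Both the rank axis and the distance axis are scaled to [0, 1]; the
    forward finite-difference derivative over a rank window is assigned
    to the window's right endpoint, and the knee is the first rank where
    it exceeds ``threshold``.  ``eps`` is the raw distance at the knee
    rank by default (``eps_scale="scaled"`` reports the [0, 1]-scaled
    value instead; for min-max-normalized input data the two coincide in
    magnitude at the printed precision).

    ``window`` is the forward-difference step in ranks; the default,
    ``max(1, round(0.05 * n))``, estimates the derivative over a 5%
    stretch of the curve so that single-rank spacing noise — inherent in
    the order statistics of thousands of neighbor distances — does not
    trigger a spurious knee.  On short curves the default reduces to the
    plain adjacent-rank forward difference.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    if n < 3:
        raise ParameterError("need at least 3 curve points")
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if np.any(np.diff(curve) < 0):
        raise ValidationError("curve must be ascending")
    span = curve[-1] - curve[0]
    if span == 0:
        raise NoKneeError("constant kNN-distance curve has no knee; supply eps manually")
    if window is None:
        window = max(1, round(KNEE_WINDOW_FRACTION * n))
    window = int(window)
    if not 1 <= window <= n - 1:
        raise ParameterError(f"window must be in [1, {n - 1}], got {window}")
    scaled = (curve - curve[0]) / span
    # d(scaled distance)/d(scaled rank); rank step is 1/(n-1) after scaling
    deriv = (scaled[window:] - scaled[:-window]) * (n - 1) / window
    exceed = np.flatnonzero(deriv > threshold)
    if exceed.size == 0:
        raise NoKneeError(
            f"derivative never exceeds {threshold}; supply eps manually"
        )
    knee_index = int(exceed[0] + window)
    if eps_scale == "raw":
        eps = float(curve[knee_index])
    elif eps_scale == "scaled":
        eps = float(scaled[knee_index])
    else:
        raise ParameterError(f"eps_scale must be 'raw' or 'scaled', got {eps_scale!r}")
    return KneeResult(curve, scaled, knee_index, eps, float(threshold))


def dbscan_cluster(points: np.ndarray, eps: float, min_pts: int) -> DbscanResult:
    """Exact DBSCAN with explicit core/border/noise point types.

    Neighborhoods are closed Euclidean balls including the point itself.
    Cluster ids are assigned in order of the lowest-indexed core point of
    each component, so the labeling is deterministic and, up to
    relabeling, invariant to input permutation.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be a 2-D array")
    if not np.isfinite(points).all():
        raise ValidationError("points contain non-finite coordinates")
    if eps <= 0:
        raise ParameterError("eps must be positive")
    if min_pts < 1:
        raise ParameterError("min_pts must be >= 1")
    n = points.shape[0]
    nn = NearestNeighbors(radius=eps).fit(points)
    neigh = nn.radius_neighbors(points, return_distance=False)
    core = np.array([idx.size >= min_pts for idx in neigh])

    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        # BFS over the eps-reachability graph restricted to core points
        labels[i] = cluster
        stack = [i]
        while stack:
            j = stack.pop()
            for nb in neigh[j]:
                if core[nb] and labels[nb] == NOISE:
                    labels[nb] = cluster
                    stack.append(nb)
        cluster += 1

    point_type = np.full(n, NOISE_TYPE, dtype=object)
    point_type[core] = CORE
    for i in range(n):
        if core[i]:
            continue
        core_nbs = neigh[i][core[neigh[i]]]
        if core_nbs.size:
            labels[i] = labels[core_nbs.min()]
            point_type[i] = BORDER
    return DbscanResult(labels, point_type.astype(str), float(eps), int(min_pts))


def remove_noise(g: GeneMatrix, r: DbscanResult, keep_border: bool = True) -> GeneMatrix:
    """Drop the noise features of a DBSCAN result, preserving order.

    ``keep_border=False`` is the strict mode that additionally discards
    border features, keeping core features only.
    """
    if len(r.labels) != g.n_genes:
        raise ValidationError(
            f"result length {len(r.labels)} does not match {g.n_genes} genes"
        )
    keep = r.point_type == CORE
    if keep_border:
        keep = keep | (r.point_type == BORDER)
    return g.select_genes(keep)


def run_denoise(g: GeneMatrix, min_pts: int = 5, knn_k: int = 4,
            derivative_threshold: float = 1.0, eps: float | None = None,
            eps_scale: str = "raw", keep_border: bool = True) -> tuple:
    """Calibrate eps (unless given), cluster, and drop noise.

    Returns ``(clean_matrix, dbscan_result, knee_result_or_None)``.  The
    kNN curve uses k = ``min_pts`` - 1 neighbors by default (the
    self-neighbor excluded), the standard kNN-distance-plot convention.
    """
    knee = None
    if eps is None:
        curve = knn_distance_curve(g.values, knn_k)
        knee = estimate_knee(curve, derivative_threshold, eps_scale=eps_scale)
        eps = knee.eps
    result = dbscan_cluster(g.values, eps, min_pts)
    clean = remove_noise(g, result, keep_border=keep_border)
    return clean, result, knee
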