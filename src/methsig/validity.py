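"""Cluster-validity indices for a labeled point set (Euclidean metric).

Implements the eight indices reported by the pipeline: Ball-Hall,
Davies-Bouldin, Dunn, G+, the generalized Dunn variants GDI11, GDI12 and
GDI31 (Bezdek-Pal delta/Delta numbering, under which GDI11 is the classic
Dunn index), and Ray-Turi.  Indices are reported raw; direction of
"better" is left to interpretation (lower is conventionally better for
Davies-Bouldin, Ball-Hall and Ray-Turi).

A seeded Lloyd k-means baseline is provided for side-by-side comparison
of a module labeling with a conventional partition of the same points.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

from .errors import ValidationError


@dataclass
class ValidityReport:
    ball_hall: float
    davies_bouldin: float
    dunn: float
    g_plus: float
    gdi11: float
    gdi12: float
    gdi31: float
    ray_turi: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_validity(points: np.ndarray, labels) -> ValidityReport:
    """All eight indices for one labeling.

    Requires at least two clusters, each non-empty.  Within-cluster
    spread statistics of singleton clusters (no internal pairs) are
    taken as zero.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[0] != labels.shape[0]:
        raise ValidationError("points and labels must align")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("validity indices require >= 2 clusters")
    groups = [np.flatnonzero(labels == u) for u in uniq]
    if any(g.size == 0 for g in groups):
        raise ValidationError("empty cluster")
    n = points.shape[0]
    D = squareform(pdist(points))

    centroids = np.array([points[g].mean(axis=0) for g in groups])
    cdists = cdist(centroids, centroids)

    # per-cluster spread
    member_to_centroid = [np.linalg.norm(points[g] - centroids[i], axis=1)
                          for i, g in enumerate(groups)]
    mean_sq_to_centroid = np.array([(d ** 2).mean() for d in member_to_centroid])
    mean_to_centroid = np.array([d.mean() for d in member_to_centroid])

    ball_hall = float(mean_sq_to_centroid.mean())

    k = len(groups)
    db_terms = []
    for a in range(k):
        ratios = [(mean_to_centroid[a] + mean_to_centroid[b]) / cdists[a, b]
                  for b in range(k) if b != a and cdists[a, b] > 0]
        # coincident centroids give an unbounded ratio
        db_terms.append(max(ratios) if ratios else np.inf)
    davies_bouldin = float(np.mean(db_terms))

    # within/between pairwise distances
    within_mask = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    pair_within = within_mask[iu]
    pair_d = D[iu]
    within_d = pair_d[pair_within]
    between_d = pair_d[~pair_within]

    diameters = np.array([D[np.ix_(g, g)].max() if g.size > 1 else 0.0 for g in groups])
    mean_within_pair = np.array(
        [D[np.ix_(g, g)][np.triu_indices(g.size, k=1)].mean() if g.size > 1 else 0.0
         for g in groups])

    max_diam = float(diameters.max())
    max_mean_within = float(mean_within_pair.max())

    min_between = np.inf
    mean_between_min = np.inf
    for a in range(k):
        for b in range(a + 1, k):
            cross = D[np.ix_(groups[a], groups[b])]
            min_between = min(min_between, float(cross.min()))
            mean_between_min = min(mean_between_min, float(cross.mean()))

    dunn = _safe_ratio(min_between, max_diam)
    gdi11 = dunn
    gdi12 = _safe_ratio(min_between, max_mean_within)
    gdi31 = _safe_ratio(mean_between_min, max_diam)

    # G+: discordant (within, between) comparisons where between < within
    n_t = n * (n - 1) // 2
    if within_d.size and between_d.size:
        sw = np.sort(within_d)
        # for each between distance: count of strictly larger within distances
        s_minus = int(np.sum(sw.size - np.searchsorted(sw, between_d, side="right")))
    else:
        s_minus = 0
    g_plus = 2.0 * s_minus / (n_t * (n_t - 1)) if n_t > 1 else 0.0

    total_mean_sq = float(np.mean(
        np.concatenate([d ** 2 for d in member_to_centroid])))
    off = cdists[np.triu_indices(k, k=1)]
    min_c = float(off.min())
    ray_turi = total_mean_sq / min_c ** 2 if min_c > 0 else float(np.inf)

    return ValidityReport(ball_hall, davies_bouldin, dunn, float(g_plus),
                          gdi11, gdi12, gdi31, float(ray_turi))


def _safe_ratio(num: float, den: float) -> float:
    if den == 0:
        return float(np.inf) if num > 0 else 0.0
    return float(num / den)


def kmeans_baseline(points: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded Lloyd k-means labels for the comparison column."""
    points = np.asarray(points, dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2 ** 31))
    return km.fit_predict(points)
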