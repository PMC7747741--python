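"""Independent brute-force reference implementations used as oracles.

Everything here is written from the textbook definitions with plain
loops over full pairwise-distance matrices, deliberately sharing no code
with the package's implementations.
"""

import numpy as np
from scipy.spatial.distance import cdist


def naive_dbscan(points, eps, min_pts):
    """DBSCAN by exhaustive neighbor lists and BFS over core points.

    Returns ``(labels, point_type)`` with cluster ids assigned in order
    of the lowest-indexed core point of each component and border points
    attached to the cluster of their lowest-indexed core neighbor.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = cdist(points, points)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]  # includes self
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    ptype = np.array(["noise"] * n, dtype=object)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        frontier = [i]
        labels[i] = cluster
        while frontier:
            j = frontier.pop()
            for nb in neighbors[j]:
                if core[nb] and labels[nb] == -1:
                    labels[nb] = cluster
                    frontier.append(nb)
        cluster += 1
    for i in range(n):
        if core[i]:
            ptype[i] = "core"
        else:
            core_nb = [j for j in neighbors[i] if core[j]]
            if core_nb:
                labels[i] = labels[min(core_nb)]
                ptype[i] = "border"
    return labels, ptype.astype(str)


def naive_average_linkage(dist):
    """O(n^3) average-linkage agglomeration on a square dissimilarity.

    Returns the list of merge heights in merge order and a function
    ``cut(t)`` giving flat cluster sets (frozensets of leaf indices) at
    threshold t.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    merges = []
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                members_a, members_b = clusters[a], clusters[b]
                h = np.mean([dist[x, y] for x in members_a for y in members_b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merges.append((set(clusters[a]), set(clusters[b]), h))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        active = sorted(clusters)
    def cut(t):
        groups = {i: {i} for i in range(n)}
        reps = {i: i for i in range(n)}
        for left, right, h in merges:
            if h <= t:
                ra = reps[min(left)]
                rb = reps[min(right)]
                if ra == rb:
                    continue
                merged = groups[ra] | groups[rb]
                for x in merged:
                    reps[x] = ra
                groups[ra] = merged
                del groups[rb]
        return {frozenset(g) for g in groups.values()}
    return heights, cut


def naive_validity(points, labels):
    """All eight cluster-validity indices by direct double loops."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    groups = [np.flatnonzero(labels == u) for u in uniq]
    n = len(points)
    d = cdist(points, points)
    cents = [points[g].mean(axis=0) for g in groups]

    def to_cent(gi):
        return [np.linalg.norm(points[x] - cents[gi]) for x in groups[gi]]

    ball_hall = np.mean([np.mean(np.array(to_cent(gi)) ** 2) for gi in range(len(groups))])

    db = []
    for a in range(len(groups)):
        vals = []
        for b in range(len(groups)):
            if a == b:
                continue
            cd = np.linalg.norm(cents[a] - cents[b])
            if cd > 0:
                vals.append((np.mean(to_cent(a)) + np.mean(to_cent(b))) / cd)
        db.append(max(vals) if vals else np.inf)
    davies_bouldin = float(np.mean(db))

    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(d[i, j])

    diam = max(
        max((d[x, y] for x in g for y in g), default=0.0) for g in groups)
    mean_within = max(
        (np.mean([d[x, y] for xi, x in enumerate(g) for y in g[xi + 1:]])
         if len(g) > 1 else 0.0) for g in groups)
    min_between = np.inf
    min_mean_between = np.inf
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            cross = [d[x, y] for x in groups[a] for y in groups[b]]
            min_between = min(min_between, min(cross))
            min_mean_between = min(min_mean_between, np.mean(cross))

    def ratio(nu, de):
        if de == 0:
            return np.inf if nu > 0 else 0.0
        return nu / de

    dunn = ratio(min_between, diam)
    gdi12 = ratio(min_between, mean_within)
    gdi31 = ratio(min_mean_between, diam)

    s_minus = sum(1 for w in within for b in between if b < w)
    n_t = n * (n - 1) // 2
    g_plus = 2.0 * s_minus / (n_t * (n_t - 1)) if n_t > 1 else 0.0

    sq = []
    for gi, g in enumerate(groups):
        sq += [np.linalg.norm(points[x] - cents[gi]) ** 2 for x in g]
    min_cd = min(np.linalg.norm(cents[a] - cents[b])
                 for a in range(len(groups)) for b in range(a + 1, len(groups)))
    ray_turi = np.mean(sq) / min_cd ** 2 if min_cd > 0 else np.inf

    return {
        "ball_hall": float(ball_hall), "davies_bouldin": davies_bouldin,
        "dunn": float(dunn), "g_plus": float(g_plus), "gdi11": float(dunn),
        "gdi12": float(gdi12), "gdi31": float(gdi31), "ray_turi": float(ray_turi),
    }


def naive_average_pcc(values):
    """Mean pairwise Pearson correlation by an explicit double loop."""
    m = len(values)
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            x, y = values[i], values[j]
            xc, yc = x - x.mean(), y - y.mean()
            out.append((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.mean(out))


def canonical_labels(labels):
    """Relabel cluster ids by order of first appearance (noise kept -1)."""
    labels = np.asarray(labels)
    mapping = {}
    out = np.full(labels.shape, -1)
    nxt = 0
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out
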