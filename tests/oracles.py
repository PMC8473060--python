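"""Brute-force reference implementations used only as test oracles.

These deliberately avoid the data structures the package uses (KD-trees,
shapely geometry, vectorized IDW) so agreement is meaningful.
"""

import numpy as np


def dbscan_bruteforce(points, eps, min_points):
    """O(n^2) DBSCAN with the package's tie-break conventions.

    Dense distance matrix, breadth-first growth of core components in
    ascending index order, border points to their lowest-indexed core
    neighbor. Returns labels (-1 noise, clusters numbered by first core).
    """
    X = np.asarray(points, float)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    adj = D <= eps
    core = adj.sum(axis=1) >= min_points  # diagonal counts the point itself
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            stack = [i]
            labels[i] = cluster
            while stack:
                p = stack.pop()
                for q in np.flatnonzero(adj[p] & core):
                    if labels[q] == -1:
                        labels[q] = cluster
                        stack.append(int(q))
            cluster += 1
    for i in range(n):
        if not core[i]:
            core_neighbors = np.flatnonzero(adj[i] & core)
            if len(core_neighbors):
                labels[i] = labels[core_neighbors[0]]
    return labels


def _point_segment_distance(p, a, b):
    ab = b - a
    t = np.dot(p - a, ab) / np.dot(ab, ab)
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (a + t * ab)))


def hull_retention_bruteforce(points_xy, hull_vertices, buffer):
    """Point-in-polygon by ray casting plus exact boundary distance.

    ``hull_vertices`` are the polygon's vertices in order (no repeat of the
    first). Retained iff inside the polygon or within ``buffer`` of an edge.
    """
    V = np.asarray(hull_vertices, float)
    m = len(V)
    keep = np.zeros(len(points_xy), dtype=bool)
    for k, p in enumerate(np.asarray(points_xy, float)):
        inside = False
        j = m - 1
        for i in range(m):
            xi, yi = V[i]
            xj, yj = V[j]
            if (yi > p[1]) != (yj > p[1]) and p[0] < (xj - xi) * (
                p[1] - yi
            ) / (yj - yi) + xi:
                inside = not inside
            j = i
        if inside:
            keep[k] = True
            continue
        d = min(
            _point_segment_distance(p, V[i], V[(i + 1) % m]) for i in range(m)
        )
        keep[k] = d <= buffer
    return keep


def idw_bruteforce(ground_xy, ground_z, query_xy, k, power):
    """Direct-summation inverse-distance weighting at query locations."""
    out = np.empty(len(query_xy))
    for i, q in enumerate(np.asarray(query_xy, float)):
        d = np.sqrt(((ground_xy - q) ** 2).sum(1))
        order = np.argsort(d, kind="stable")[:k]
        dk, zk = d[order], np.asarray(ground_z)[order]
        if dk[0] < 1e-9:
            out[i] = zk[0]
        else:
            w = 1.0 / dk**power
            out[i] = float((w * zk).sum() / w.sum())
    return out


def partition_signature(labels):
    """Canonical form of a clustering for exact-partition comparison:
    frozenset of frozensets of member indices, plus the noise set."""
    clusters = {}
    noise = []
    for i, lab in enumerate(labels):
        if lab < 0:
            noise.append(i)
        else:
            clusters.setdefault(lab, []).append(i)
    return (
        frozenset(frozenset(v) for v in clusters.values()),
        frozenset(noise),
    )
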