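"""Independent brute-force oracles used to check clustering and spread.

These deliberately avoid the code paths of the package: neighborhoods and
density-connectivity are computed exhaustively from the distance matrix.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """Exhaustive DBSCAN: returns (core_components, noise_indices).

    core_components: set of frozensets partitioning the core points by
    density-connectivity (transitive closure of eps-reachability among
    cores). noise_indices: points that are neither core nor within eps of
    any core point. Border-point cluster assignment is ambiguous by
    definition and therefore not part of the oracle's output.
    """
    n = len(points)
    if n == 0:
        return set(), frozenset()
    dist = cdist(points, points)
    neighbors = dist <= eps
    core = neighbors.sum(axis=1) >= min_pts

    # Transitive closure of eps-adjacency restricted to core points.
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    core_idx = np.flatnonzero(core)
    for i in core_idx:
        for j in core_idx:
            if neighbors[i, j]:
                union(int(i), int(j))

    components: dict[int, set[int]] = {}
    for i in core_idx:
        components.setdefault(find(int(i)), set()).add(int(i))

    noise = frozenset(
        int(i)
        for i in range(n)
        if not core[i] and not any(neighbors[i, j] for j in core_idx)
    )
    return {frozenset(c) for c in components.values()}, noise


def brute_twcv(points: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation: sum over clusters of mean squared deviation."""
    total = 0.0
    for c in sorted(set(labels.tolist())):
        if c == -1:
            continue
        members = points[labels == c]
        centroid = members.mean(axis=0)
        sq = [float(np.dot(x - centroid, x - centroid)) for x in members]
        total += sum(sq) / len(sq)
    return total
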