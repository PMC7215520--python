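"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: shortest paths
by Floyd–Warshall on the dense adjacency, betweenness by exhaustive
enumeration of all shortest paths, and superposition by a fine grid search
over rotations.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


def floyd_warshall(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on a boolean adjacency matrix."""
    n = adjacency.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[adjacency] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def per_node_average_path(adjacency: np.ndarray) -> np.ndarray:
    """Average distance to reachable partners, NaN when none are reachable."""
    d = floyd_warshall(adjacency)
    n = d.shape[0]
    out = np.full(n, np.nan)
    for v in range(n):
        reach = [d[v, t] for t in range(n) if t != v and d[v, t] < INF]
        if reach:
            out[v] = sum(reach) / len(reach)
    return out


def _all_shortest_paths(adjacency: np.ndarray, s: int, t: int, dist: np.ndarray):
    """Enumerate every shortest s-t path by depth-first walk down the distance field."""
    if dist[s, t] == INF:
        return
    n = adjacency.shape[0]

    def walk(node, path):
        if node == t:
            yield path
            return
        for nxt in range(n):
            if adjacency[node, nxt] and dist[nxt, t] == dist[node, t] - 1:
                yield from walk(nxt, path + [nxt])

    yield from walk(s, [s])


def betweenness_by_enumeration(adjacency: np.ndarray) -> np.ndarray:
    """Raw betweenness: sum over unordered pairs of the fraction of shortest
    paths through each intermediate vertex."""
    n = adjacency.shape[0]
    dist = floyd_warshall(adjacency)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = list(_all_shortest_paths(adjacency, s, t, dist))
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray, coarse: int = 24) -> float:
    """Minimum RMSD over proper rotations by Euler-angle grid refinement."""
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_at(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ r.T - ref) ** 2, axis=1)))

    best, best_angles = INF, None
    grid = np.linspace(-np.pi, np.pi, coarse, endpoint=False)
    for a in grid:
        for b in np.linspace(-np.pi / 2, np.pi / 2, coarse // 2):
            for c in grid:
                v = rmsd_at((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    # local refinement around the best grid point
    step = 2 * np.pi / coarse
    angles = np.array(best_angles)
    for _ in range(40):
        improved = False
        for i in range(3):
            for sign in (-1, 1):
                cand = angles.copy()
                cand[i] += sign * step
                v = rmsd_at(cand)
                if v < best:
                    best, angles, improved = v, cand, True
        if not improved:
            step /= 2
            if step < 1e-10:
                break
    return float(best)


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric boolean adjacency of an Erdős–Rényi graph."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return adj | adj.T
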