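"""Independent brute-force oracles for the network metrics.

Everything here is computed from first principles — Floyd–Warshall
distances with explicit shortest-path counting, power iteration,
triangle enumeration — and deliberately shares no code path with the
package implementation.
"""

from __future__ import annotations

import numpy as np

TIE_TOL = 1e-9


def distance_matrix(n: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """All-pairs shortest-path distances by Floyd–Warshall."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j, dist in edges:
        d[i, j] = min(d[i, j], dist)
        d[j, i] = d[i, j]
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def count_shortest_paths(
    n: int, edges: list[tuple[int, int, float]], d: np.ndarray, s: int
) -> np.ndarray:
    """Number of shortest paths from s to every node, by DP in distance order."""
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, dist in edges:
        adj[i].append((j, dist))
        adj[j].append((i, dist))
    sigma = np.zeros(n)
    sigma[s] = 1.0
    order = np.argsort(d[s])
    for v in order:
        if v == s or not np.isfinite(d[s, v]):
            continue
        for u, dist in adj[v]:
            if abs(d[s, u] + dist - d[s, v]) < TIE_TOL:
                sigma[v] += sigma[u]
    return sigma


def betweenness(n: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Shortest-path betweenness with fractional attribution among ties."""
    d = distance_matrix(n, edges)
    sigma = np.array([count_shortest_paths(n, edges, d, s) for s in range(n)])
    btw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < TIE_TOL:
                    btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


def closeness(n: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Bounded reachable-set closeness: ((r-1)/(n-1)) * ((r-1)/sum d)."""
    d = distance_matrix(n, edges)
    out = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(d[v])
        r = int(reach.sum())  # includes v itself
        if r < 2:
            continue
        tot = d[v][reach].sum()
        out[v] = ((r - 1) / (n - 1)) * ((r - 1) / tot)
    return out


def clustering(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Binary local clustering by neighbour-pair counting."""
    adj = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    out = np.zeros(n)
    for v in range(n):
        nb = sorted(adj[v])
        k = len(nb)
        if k < 2:
            continue
        ties = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if nb[b] in adj[nb[a]]
        )
        out[v] = ties / (k * (k - 1) / 2)
    return out


def eigenvector(n: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Leading-eigenvector scores via shifted power iteration per component.

    Matches the package convention: component vectors L2-normalised,
    nonnegative, whole vector rescaled to max 1; isolates 0.
    """
    a = np.zeros((n, n))
    for i, j, w in edges:
        a[i, j] += w
        a[j, i] += w
    # find components
    seen = np.zeros(n, dtype=bool)
    scores = np.zeros(n)
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in np.nonzero(a[v])[0]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(int(u))
        if len(comp) < 2:
            continue
        comp = sorted(comp)
        sub = a[np.ix_(comp, comp)]
        shift = 0.1 * sub.sum(axis=1).max() + 1.0
        x = np.ones(len(comp))
        for _ in range(100000):
            y = sub @ x + shift * x
            y /= np.linalg.norm(y)
            if np.linalg.norm(y - x) < 1e-13:
                x = y
                break
            x = y
        x = np.abs(x)
        for v, val in zip(comp, x):
            scores[v] = val
    top = scores.max()
    if top > 0:
        scores /= top
    return scores


def global_metrics(
    n: int, edges: list[tuple[int, int, float]]
) -> dict:
    """Mean degree, diameter (connected pairs), transitivity, density."""
    d = distance_matrix(n, edges)
    finite = d[np.isfinite(d)]
    diameter = float(finite.max()) if finite.size else 0.0
    deg = np.zeros(n)
    binary = [(i, j) for i, j, _ in edges]
    for i, j in binary:
        deg[i] += 1
        deg[j] += 1
    # transitivity: 3 * triangles / connected triples
    adj = [set() for _ in range(n)]
    for i, j in binary:
        adj[i].add(j)
        adj[j].add(i)
    triangles = 0
    for i, j in binary:
        triangles += len(adj[i] & adj[j])
    triangles //= 3
    triples = int((deg * (deg - 1) / 2).sum())
    m = len(binary)
    return {
        "mean_degree": float(deg.mean()),
        "diameter": diameter,
        "transitivity": 3.0 * triangles / triples if triples else 0.0,
        "density": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
    }


def random_graph(
    rng: np.random.Generator, n: int, p: float, weighted: bool
) -> list[tuple[int, int, float]]:
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.5, 3.0)) if weighted else 1.0
                edges.append((i, j, w))
    return edges
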