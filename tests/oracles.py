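"""Independent brute-force oracles for the network metrics.

Each oracle evaluates its metric's definition literally (explicit loops,
exhaustive path enumeration), staying independent of the vectorised /
library-backed implementations it cross-checks.
"""

from __future__ import annotations

import numpy as np


def cc_brute(w: np.ndarray) -> float:
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    Q = w.shape[0]
    a = (w > 0).astype(int)
    ccs = []
    for i in range(Q):
        nbrs = {j for j in range(Q) if j != i and (a[i, j] or a[j, i])}
        d = len(nbrs)
        s = w[i].sum()
        if d <= 1 or s == 0:
            ccs.append(0.0)
            continue
        total = 0.0
        for j in range(Q):
            for h in range(Q):
                total += (w[i, j] + w[i, h]) / 2.0 * a[i, j] * a[j, h] * a[i, h]
        ccs.append(total / (s * (d - 1)))
    return float(np.mean(ccs))


def mjl_brute(w: np.ndarray) -> float:
    w = np.asarray(w, dtype=float)
    Q = w.shape[0]
    total = 0.0
    for i in range(Q):
        for j in range(Q):
            total += abs(i - j) * w[i, j]
    return total / Q


def _bfs_dist(adj: list[list[int]], src: int, Q: int) -> list[float]:
    dist = [float("inf")] * Q
    dist[src] = 0
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] == float("inf"):
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj, dist, src, dst):
    """Enumerate every shortest path src -> dst by DFS along decreasing dist."""
    if dist[dst] == float("inf"):
        return
    stack = [(src, [src])]
    while stack:
        node, path = stack.pop()
        if node == dst:
            yield path
            continue
        for v in adj[node]:
            if dist[v] == len(path) and dist[dst] >= dist[v]:
                # only extend along a shortest-path DAG toward dst
                stack.append((v, path + [v]))


def bc_brute(w: np.ndarray) -> float:
    """Average normalised betweenness by exhaustive shortest-path listing."""
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    Q = w.shape[0]
    adj = [[j for j in range(Q) if w[i, j] > 0] for i in range(Q)]
    through = np.zeros(Q)
    for i in range(Q):
        dist_i = _bfs_dist(adj, i, Q)
        for j in range(Q):
            if i == j or dist_i[j] == float("inf"):
                continue
            paths = [
                p
                for p in _all_shortest_paths(adj, dist_i, i, j)
                if len(p) - 1 == dist_i[j]
            ]
            sigma = len(paths)
            for u in range(Q):
                if u in (i, j):
                    continue
                sigma_u = sum(1 for p in paths if u in p[1:-1])
                through[u] += sigma_u / sigma
    norm = (Q - 1) * (Q - 2)
    return float(np.mean(through / norm))


def mo_brute(w: np.ndarray, labels) -> float:
    """Modularity of a given partition, evaluated with explicit loops."""
    w = np.array(w, dtype=float)
    Q = w.shape[0]
    ws = np.zeros((Q, Q))
    for i in range(Q):
        for j in range(Q):
            if i != j:
                ws[i, j] = (w[i, j] + w[j, i]) / 2.0
    E = ws.sum() / 2.0
    labels = np.asarray(labels)
    score = 0.0
    for m in set(labels.tolist()):
        nodes = [i for i in range(Q) if labels[i] == m]
        e_m = sum(ws[i, j] for i in nodes for j in nodes) / 2.0
        d_m = sum(ws[i, j] for i in nodes for j in range(Q))
        score += e_m / E - (d_m / (2.0 * E)) ** 2
    return float(score)


def lee_brute(w: np.ndarray) -> float:
    """Definition-level Laplacian Estrada index: build L entrywise, sum exp."""
    w = np.array(w, dtype=float)
    Q = w.shape[0]
    ws = np.zeros((Q, Q))
    for i in range(Q):
        for j in range(Q):
            if i != j:
                ws[i, j] = (w[i, j] + w[j, i]) / 2.0
    lap = np.zeros((Q, Q))
    for i in range(Q):
        lap[i, i] = ws[i].sum()
        for j in range(Q):
            if i != j:
                lap[i, j] = -ws[i, j]
    mu = np.linalg.eigvalsh(lap)
    return float(sum(np.exp(m) for m in mu))


def random_weight_matrix(rng: np.random.Generator, Q: int, density: float = 0.5,
                         row_stochastic: bool = False) -> np.ndarray:
    """A random sparse nonnegative weight matrix, optionally row-normalised."""
    w = rng.random((Q, Q)) * (rng.random((Q, Q)) < density)
    if row_stochastic:
        rowsum = w.sum(axis=1)
        nz = rowsum > 0
        w[nz] = w[nz] / rowsum[nz, None]
    return w
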