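"""Independent brute-force oracles for graph metrics.

Everything here is written from the definitions using exhaustive loops only
(Floyd-Warshall distances, neighbour-pair triangle counts, shortest-path
enumeration for betweenness), deliberately sharing no code with the package.
Intended for graphs of at most ~10 nodes.
"""

from __future__ import annotations

import itertools

import numpy as np


def fw_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        total += links / (k * (k - 1) / 2)
    return total / n


def path_length_oracle(adj: np.ndarray) -> float:
    d = fw_distances(adj)
    vals = [d[i, j] for i in range(len(adj)) for j in range(len(adj))
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else np.inf


def global_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = fw_distances(adj)
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]))
    return total / (n * (n - 1))


def local_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += global_efficiency_oracle(sub)
    return total / n


def nodal_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = fw_distances(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n)
                     if j != i and np.isfinite(d[i, j])) / (n - 1)
    return out


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Enumerate every shortest s-t path by depth-first search along distances."""
    d = fw_distances(adj)
    if not np.isfinite(d[s, t]) or s == t:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in range(adj.shape[0]):
            if adj[u, v] and d[s, v] == d[s, u] + 1 and d[v, t] == d[s, t] - d[s, v]:
                extend(path + [v])

    extend([s])
    return paths


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by explicit shortest-path enumeration."""
    n = adj.shape[0]
    bw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bw[v] += 1.0 / len(paths)
    return bw / ((n - 1) * (n - 2) / 2)


def random_adjacency(n: int, n_edges: int, rng: np.random.Generator) -> np.ndarray:
    pairs = list(itertools.combinations(range(n), 2))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    adj = np.zeros((n, n), dtype=bool)
    for k in chosen:
        i, j = pairs[k]
        adj[i, j] = adj[j, i] = True
    return adj
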