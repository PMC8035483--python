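"""Topological metrics on binary undirected networks.

Global: clustering coefficient Cp, characteristic path length Lp, global and
local efficiency, and the small-world normalizations gamma = Cp / <Cp_null>,
lambda = Lp / <Lp_null>, sigma = gamma / lambda against degree-preserving
rewired null networks (Maslov-Sneppen double-edge swaps).

Nodal: degree, nodal efficiency, and betweenness centrality (normalized by
(N-1)(N-2)/2 so values are comparable across sparsity levels).

Conventions on fragmented graphs: unreachable pairs are excluded from Lp
(mean over connected pairs only) but contribute zero to efficiencies; the
number of connected components is always reported.

Shortest paths are computed by scipy's csgraph machinery and betweenness by
igraph; the surrounding reductions implement the conventions above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import igraph as ig
import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .netcon import BinaryNetwork


class EstimabilityError(ValueError):
    """Raised when the small-world normalization is not estimable."""


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    eglob: float
    eloc: float
    n_components: int
    gamma: float | None = None
    lambda_: float | None = None
    sigma: float | None = None


@dataclass
class NodalMetrics:
    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray


@njit(cache=True)
def _bfs_all_pairs(adj):  # pragma: no cover - jitted
    n = adj.shape[0]
    dist = np.full((n, n), -1, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        dist[s, s] = 0
        head, tail = 0, 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf for unreachable pairs)."""
    d = _bfs_all_pairs(np.ascontiguousarray(adj, dtype=np.bool_)).astype(float)
    d[d < 0] = np.inf
    return d


@njit(cache=True)
def _cp_lp_kernel(adj):  # pragma: no cover - jitted
    n = adj.shape[0]
    deg = np.zeros(n, np.int32)
    for i in range(n):
        c = 0
        for j in range(n):
            if adj[i, j]:
                c += 1
        deg[i] = c
    indptr = np.zeros(n + 1, np.int32)
    for i in range(n):
        indptr[i + 1] = indptr[i] + deg[i]
    nbrs = np.empty(indptr[n], np.int32)
    for i in range(n):
        p = indptr[i]
        for j in range(n):
            if adj[i, j]:
                nbrs[p] = j
                p += 1
    cp_sum = 0.0
    for i in range(n):
        k = deg[i]
        if k < 2:
            continue
        t = 0
        for a in range(indptr[i], indptr[i + 1]):
            u = nbrs[a]
            for b in range(a + 1, indptr[i + 1]):
                if adj[u, nbrs[b]]:
                    t += 1
        cp_sum += 2.0 * t / (k * (k - 1))
    cp = cp_sum / n
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    s_sum = 0.0
    s_cnt = 0
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for a in range(indptr[u], indptr[u + 1]):
                v = nbrs[a]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for i in range(n):
            if i != s and dist[i] > 0:
                s_sum += dist[i]
                s_cnt += 1
    lp = s_sum / s_cnt if s_cnt > 0 else np.inf
    return cp, lp


def _cp_lp(adj: np.ndarray) -> tuple[float, float]:
    """Clustering coefficient and characteristic path length only (null-model path)."""
    cp, lp = _cp_lp_kernel(np.ascontiguousarray(adj, dtype=np.bool_))
    return float(cp), float(lp)


def clustering_per_node(adj: np.ndarray) -> np.ndarray:
    """Local clustering: closed triangles over possible neighbour pairs (k<2 -> 0)."""
    a = adj.astype(float)
    k = a.sum(axis=0)
    tri = ((a @ a) * a).sum(axis=1) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_metrics(net: BinaryNetwork) -> GlobalMetrics:
    """Cp, Lp, Eglob, Eloc and component count (normalizations unset)."""
    adj = net.adjacency
    if net.n_edges < 1:
        raise EstimabilityError("empty graph has no defined metrics")
    # summing sorted per-node values makes Cp exactly invariant to relabeling
    cp = float(np.sort(clustering_per_node(adj)).sum() / adj.shape[0])
    d = _distances(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else np.inf
    eglob = _efficiency_from_distances(d)
    eloc_terms = np.zeros(adj.shape[0])
    for i in range(adj.shape[0]):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        eloc_terms[i] = _efficiency_from_distances(_distances(sub))
    ncomp = connected_components(csr_matrix(adj.astype(np.int8)), directed=False,
                                 return_labels=False)
    return GlobalMetrics(cp=cp, lp=lp, eglob=eglob, eloc=float(eloc_terms.mean()),
                         n_components=int(ncomp))


def nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    """Degree, nodal efficiency, and normalized betweenness per node."""
    adj = net.adjacency
    if net.n_edges < 1:
        raise EstimabilityError("empty graph has no defined metrics")
    n = adj.shape[0]
    deg = adj.sum(axis=0).astype(int)
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (n - 1)
    g = ig.Graph.Adjacency(adj.tolist(), mode="undirected")
    bw = np.asarray(g.betweenness(), dtype=float)
    norm = (n - 1) * (n - 2) / 2.0
    return NodalMetrics(degree=deg, nodal_efficiency=ne, betweenness=bw / norm)


# ---------------------------------------------------------------------------
# Degree-preserving null model
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rewire_kernel(adj, edges, target, max_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edges.shape[0]
    successes = 0
    attempts = 0
    while successes < target and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        successes += 1
    return successes


def rewire_preserving_degree(net: BinaryNetwork, swaps_per_edge: int = 10,
                             seed: int = 0) -> BinaryNetwork:
    """Randomize wiring by double-edge swaps, preserving every node's degree.

    Attempts are capped at 10x the target swap count; if no legal swap exists
    (e.g. a complete graph) the input topology is returned unchanged with a
    warning recording the swap deficit.
    """
    if net.n_edges < 2:
        raise EstimabilityError("need at least 2 edges to rewire")
    adj = net.adjacency.copy()
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    target = int(swaps_per_edge * net.n_edges)
    successes = _rewire_kernel(adj, edges, target, 10 * target, int(seed) % (2**31))
    if successes < target:
        warnings.warn(
            f"rewiring achieved {successes}/{target} swaps before the attempt cap",
            RuntimeWarning,
            stacklevel=2,
        )
    return BinaryNetwork(adj, sparsity=net.sparsity, n_edges=net.n_edges)


@njit(cache=True)
def _null_ensemble_kernel(adj0, edges0, n_null, target, seed):  # pragma: no cover - jitted
    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    for m in range(n_null):
        adj = adj0.copy()
        edges = edges0.copy()
        _rewire_kernel(adj, edges, target, 10 * target, (seed + 7919 * m) % 2147483648)
        null_cp[m], null_lp[m] = _cp_lp_kernel(adj)
    return null_cp, null_lp


def small_world_normalization(net: BinaryNetwork, n_null: int = 100,
                              swaps_per_edge: int = 10, seed: int = 0
                              ) -> tuple[float, float, float]:
    """gamma, lambda, sigma against an ensemble of degree-matched nulls.

    sigma = gamma / lambda is considered estimable when the null means of Cp
    and Lp are finite and positive; otherwise an EstimabilityError is raised.
    """
    if n_null < 1:
        raise EstimabilityError("need at least one null network")
    cp, lp = _cp_lp(net.adjacency)
    adj = np.ascontiguousarray(net.adjacency, dtype=np.bool_)
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    target = int(swaps_per_edge * net.n_edges)
    null_cp, null_lp = _null_ensemble_kernel(adj, edges, n_null, target,
                                             int(seed) % (2**31))
    mean_cp = float(null_cp.mean())
    mean_lp = float(null_lp.mean())
    if not (np.isfinite(mean_cp) and np.isfinite(mean_lp)) or mean_cp <= 0 or mean_lp <= 0:
        raise EstimabilityError("sigma not estimable: degenerate null ensemble")
    gamma = cp / mean_cp
    lambda_ = lp / mean_lp
    if not np.isfinite(gamma) or not np.isfinite(lambda_) or lambda_ <= 0:
        raise EstimabilityError("sigma not estimable: gamma or lambda degenerate")
    return float(gamma), float(lambda_), float(gamma / lambda_)


def global_metrics_normalized(net: BinaryNetwork, n_null: int = 100,
                              swaps_per_edge: int = 10, seed: int = 0) -> GlobalMetrics:
    """Global metrics with gamma/lambda/sigma filled in."""
    gm = global_metrics(net)
    gamma, lambda_, sigma = small_world_normalization(
        net, n_null=n_null, swaps_per_edge=swaps_per_edge, seed=seed
    )
    return replace(gm, gamma=gamma, lambda_=lambda_, sigma=sigma)
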