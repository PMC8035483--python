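"""Subject-level connectivity: partial-correlation matrix and binarization.

The connectome edge weight between two regions is their partial correlation
-- the correlation remaining after regressing out all other regions -- read
off the precision matrix of the (optionally shrinkage-regularized) sample
covariance: pcorr(i, j) = -Omega_ij / sqrt(Omega_ii * Omega_jj).  Binary
networks retain the strongest |pcorr| edges at a target sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import TimeSeriesMatrix


class NetconError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """N x N symmetric partial-correlation matrix, zero diagonal."""

    values: np.ndarray
    region_labels: list[str]
    shrinkage: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise NetconError("connectivity matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 0:
            raise NetconError("diagonal must be exactly zero")
        if np.abs(v).max() > 1 + 1e-9:
            raise NetconError("partial correlations must lie in [-1, 1]")
        self.values = (v + v.T) / 2.0

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected simple graph at a given sparsity, as a boolean adjacency."""

    adjacency: np.ndarray
    sparsity: float
    n_edges: int

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(a, a.T):
            raise NetconError("adjacency must be symmetric")
        if a.diagonal().any():
            raise NetconError("self-loops are not allowed")
        if int(np.triu(a, 1).sum()) != self.n_edges:
            raise NetconError("n_edges inconsistent with adjacency")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)


def partial_correlation_matrix(ts: TimeSeriesMatrix, shrinkage: float = 0.8) -> ConnectivityMatrix:
    """Partial correlations from the precision of the sample covariance.

    Only volumes surviving the scrub mask enter the covariance.  ``shrinkage``
    blends the sample covariance toward its own diagonal,
    (1 - a) * S + a * diag(S), which conditions the inversion when the number
    of retained volumes is not much larger than the number of regions.
    """
    if shrinkage < 0 or shrinkage >= 1:
        raise NetconError("shrinkage must lie in [0, 1)")
    x = ts.masked_values()
    t, n = x.shape
    if t < 3:
        raise NetconError("need at least 3 retained volumes")
    x = x - x.mean(axis=0)
    cov = x.T @ x / (t - 1)
    reg = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    try:
        omega = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:
        raise NetconError(
            "covariance is not invertible at this shrinkage; increase shrinkage"
        ) from exc
    if not np.all(np.isfinite(omega)) or np.linalg.cond(reg) > 1e12:
        raise NetconError(
            "covariance is numerically singular at this shrinkage; increase shrinkage"
        )
    d = np.sqrt(np.diag(omega))
    p = -omega / np.outer(d, d)
    p = np.clip((p + p.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(p, 0.0)
    return ConnectivityMatrix(p, list(ts.region_labels), shrinkage)


def edge_count_at_sparsity(n_regions: int, sparsity: float) -> int:
    """Number of retained edges: round-half-up of S * N(N-1)/2."""
    m = n_regions * (n_regions - 1) // 2
    return int(np.floor(sparsity * m + 0.5))


def binarize_at_sparsity(conn: ConnectivityMatrix, sparsity: float,
                         use_absolute: bool = True) -> BinaryNetwork:
    """Keep the E strongest edges at the requested sparsity.

    Edges are ranked by |partial correlation| (or signed value when
    ``use_absolute`` is False); ties break by ascending (row, column) pairs,
    making thresholds nested: the edge set at S is a subset of the set at any
    larger S.
    """
    if not 0 < sparsity < 1:
        raise NetconError("sparsity must lie in (0, 1)")
    n = conn.n_regions
    e = edge_count_at_sparsity(n, sparsity)
    if e < 1:
        raise NetconError("sparsity too small: no edges would remain")
    iu, ju = np.triu_indices(n, 1)
    w = conn.values[iu, ju]
    key = np.abs(w) if use_absolute else w
    order = np.lexsort((ju, iu, -key))
    sel = order[:e]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[sel], ju[sel]] = True
    adj |= adj.T
    return BinaryNetwork(adj, sparsity=e / (n * (n - 1) // 2), n_edges=e)


def write_connectivity_tsv(conn: ConnectivityMatrix, path) -> None:
    """Write an N x N matrix TSV with region labels as the header row."""
    import pandas as pd

    pd.DataFrame(conn.values, columns=conn.region_labels).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_connectivity_tsv(path, shrinkage: float = 0.0) -> ConnectivityMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns), shrinkage)


def write_adjacency_tsv(net: BinaryNetwork, path, region_labels: list[str] | None = None) -> None:
    """Write a 0/1 adjacency TSV (round-trippable by the matrix readers)."""
    import pandas as pd

    labels = region_labels or [f"R{i:03d}" for i in range(net.n_nodes)]
    pd.DataFrame(net.adjacency.astype(int), columns=labels).to_csv(
        path, sep="\t", index=False
    )
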