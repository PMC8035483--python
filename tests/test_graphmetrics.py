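import numpy as np
import pytest

from connsweep.graphmetrics import (
    EstimabilityError,
    global_metrics,
    global_metrics_normalized,
    nodal_metrics,
    rewire_preserving_degree,
    small_world_normalization,
)
from connsweep.netcon import BinaryNetwork

from oracles import (
    betweenness_oracle,
    clustering_oracle,
    global_efficiency_oracle,
    local_efficiency_oracle,
    nodal_efficiency_oracle,
    path_length_oracle,
    random_adjacency,
)


def net_from_adj(adj):
    adj = np.asarray(adj, dtype=bool)
    e = int(np.triu(adj, 1).sum())
    return BinaryNetwork(adj, sparsity=e / (len(adj) * (len(adj) - 1) / 2), n_edges=e)


def complete_graph(n):
    adj = ~np.eye(n, dtype=bool)
    return net_from_adj(adj)


def path_graph(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return net_from_adj(adj)


def star_graph(n_leaves):
    adj = np.zeros((n_leaves + 1, n_leaves + 1), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return net_from_adj(adj)


def ring_lattice(n, k):
    """Each node joined to its k nearest neighbours (k/2 on each side)."""
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            adj[i, j] = adj[j, i] = True
    return net_from_adj(adj)


class TestGlobalMetrics:
    def test_complete_graph_all_ones(self):
        gm = global_metrics(complete_graph(5))
        assert gm.cp == 1.0 and gm.lp == 1.0 and gm.eglob == 1.0 and gm.eloc == 1.0
        assert gm.n_components == 1

    def test_path_graph_closed_forms(self):
        gm = global_metrics(path_graph(3))
        assert gm.cp == 0.0
        assert gm.lp == pytest.approx(4 / 3)
        assert gm.eglob == pytest.approx(5 / 6)
        assert gm.eloc == 0.0

    def test_ring_lattice_clustering_closed_form(self):
        k = 4
        gm = global_metrics(ring_lattice(20, k))
        assert gm.cp == pytest.approx(3 * (k - 2) / (4 * (k - 1)))  # = 0.5
        assert gm.lp == pytest.approx(path_length_oracle(ring_lattice(20, k).adjacency))

    def test_fragmented_graph_conventions(self):
        # two components: a triangle and an isolated edge
        adj = np.zeros((5, 5), dtype=bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4)]:
            adj[i, j] = adj[j, i] = True
        gm = global_metrics(net_from_adj(adj))
        assert gm.n_components == 2
        # Lp over connected pairs only: triangle pairs at 1, the edge pair at 1
        assert gm.lp == 1.0
        # unreachable pairs contribute zero to efficiency
        assert gm.eglob == pytest.approx((6 + 2) / 20)

    def test_empty_graph_rejected(self):
        with pytest.raises(Exception):
            global_metrics(net_from_adj(np.zeros((4, 4), dtype=bool)))

    def test_oracle_equivalence_on_random_graphs(self, rng):
        for n, e in [(5, 6), (6, 9), (6, 12), (8, 12), (8, 20)]:
            for _ in range(4):
                adj = random_adjacency(n, e, rng)
                gm = global_metrics(net_from_adj(adj))
                assert gm.cp == pytest.approx(clustering_oracle(adj), abs=1e-12)
                assert gm.lp == pytest.approx(path_length_oracle(adj), abs=1e-12)
                assert gm.eglob == pytest.approx(global_efficiency_oracle(adj), abs=1e-12)
                assert gm.eloc == pytest.approx(local_efficiency_oracle(adj), abs=1e-12)


class TestNodalMetrics:
    def test_star_centre_dominates(self):
        nm = nodal_metrics(star_graph(4))
        assert nm.degree[0] == 4 and (nm.degree[1:] == 1).all()
        assert nm.betweenness[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nm.betweenness[1:], 0.0)

    def test_path_nodal_efficiency(self):
        nm = nodal_metrics(path_graph(3))
        assert nm.nodal_efficiency[1] == pytest.approx(1.0)
        assert nm.nodal_efficiency[0] == pytest.approx(0.75)
        assert nm.nodal_efficiency[2] == pytest.approx(0.75)

    def test_degree_sums_to_twice_edges(self, rng):
        adj = random_adjacency(8, 14, rng)
        net = net_from_adj(adj)
        nm = nodal_metrics(net)
        assert nm.degree.sum() == 2 * net.n_edges

    def test_oracle_equivalence_on_random_graphs(self, rng):
        for seed in range(20):
            adj = random_adjacency(8, 12, np.random.default_rng(seed))
            nm = nodal_metrics(net_from_adj(adj))
            np.testing.assert_allclose(nm.betweenness, betweenness_oracle(adj), atol=1e-12)
            np.testing.assert_allclose(
                nm.nodal_efficiency, nodal_efficiency_oracle(adj), atol=1e-12
            )

    def test_networkx_cross_check(self, rng):
        nx = pytest.importorskip("networkx")
        adj = random_adjacency(12, 30, rng)
        nm = nodal_metrics(net_from_adj(adj))
        g = nx.from_numpy_array(adj.astype(int))
        bw = nx.betweenness_centrality(g, normalized=True)
        np.testing.assert_allclose(nm.betweenness, [bw[i] for i in range(12)], atol=1e-12)


class TestRewiring:
    def test_complete_graph_returned_unchanged(self):
        net = complete_graph(4)
        with pytest.warns(RuntimeWarning):
            out = rewire_preserving_degree(net, swaps_per_edge=5, seed=1)
        np.testing.assert_array_equal(out.adjacency, net.adjacency)

    def test_degree_sequence_preserved(self, rng):
        for seed in range(10):
            adj = random_adjacency(30, 60, np.random.default_rng(seed))
            net = net_from_adj(adj)
            out = rewire_preserving_degree(net, swaps_per_edge=10, seed=seed)
            np.testing.assert_array_equal(out.degrees, net.degrees)
            assert not np.array_equal(out.adjacency, net.adjacency)
            assert not out.adjacency.diagonal().any()

    def test_lattice_clustering_destroyed(self):
        net = ring_lattice(50, 6)
        cp0 = global_metrics(net).cp
        for seed in range(10):
            null = rewire_preserving_degree(net, swaps_per_edge=10, seed=seed)
            assert global_metrics(null).cp < cp0

    def test_reproducible_given_seed(self):
        net = ring_lattice(40, 4)
        a = rewire_preserving_degree(net, seed=99)
        b = rewire_preserving_degree(net, seed=99)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestSmallWorldNormalization:
    def test_sigma_is_gamma_over_lambda(self):
        net = ring_lattice(40, 6)
        gamma, lambda_, sigma = small_world_normalization(net, n_null=10, seed=5)
        assert sigma == gamma / lambda_

    def test_watts_strogatz_regime_is_small_world(self):
        nx = pytest.importorskip("networkx")
        for seed in range(5):
            g = nx.watts_strogatz_graph(90, 16, 0.05, seed=seed)
            adj = nx.to_numpy_array(g).astype(bool)
            _, _, sigma = small_world_normalization(net_from_adj(adj), n_null=100, seed=seed)
            assert sigma > 1

    def test_degree_matched_random_self_normalizes(self):
        net = ring_lattice(90, 16)
        null = rewire_preserving_degree(net, swaps_per_edge=10, seed=0)
        gamma, lambda_, _ = small_world_normalization(null, n_null=50, seed=1)
        assert gamma == pytest.approx(1.0, abs=0.1)
        assert lambda_ == pytest.approx(1.0, abs=0.1)

    def test_normalized_global_metrics_filled(self):
        net = ring_lattice(30, 4)
        gm = global_metrics_normalized(net, n_null=10, seed=2)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lambda_)

    def test_no_nulls_rejected(self):
        with pytest.raises(EstimabilityError):
            small_world_normalization(ring_lattice(20, 4), n_null=0)


class TestInvariances:
    def test_metrics_invariant_under_relabeling(self, rng):
        adj = random_adjacency(10, 20, rng)
        gm = global_metrics(net_from_adj(adj))
        for _ in range(10):
            perm = rng.permutation(10)
            padj = adj[np.ix_(perm, perm)]
            pgm = global_metrics(net_from_adj(padj))
            assert pgm.cp == gm.cp
            assert pgm.lp == gm.lp
            nm = nodal_metrics(net_from_adj(adj))
            pnm = nodal_metrics(net_from_adj(padj))
            np.testing.assert_array_equal(pnm.degree, nm.degree[perm])

    def test_global_efficiency_bounds_inverse_path_length(self, rng):
        # harmonic mean of distances >= arithmetic-mean reciprocal on connected graphs
        for seed in range(10):
            adj = random_adjacency(9, 22, np.random.default_rng(seed))
            gm = global_metrics(net_from_adj(adj))
            if gm.n_components == 1:
                assert gm.eglob >= 1 / gm.lp - 1e-12
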