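import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plvnet.connectivity import ConnectivityMatrix
from plvnet.graphnet import (
    BinaryGraph,
    binarize,
    characteristic_path_length,
    clustering_coefficient,
    network_metrics,
    node_degrees,
    shortest_path_matrix,
    write_adjacency_csv,
    write_edge_list,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)


def oracle_clustering(adj):
    """Mean CC by exhaustive neighbour-pair counting."""
    n = len(adj)
    ccs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            ccs.append(0.0)
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a]][nbrs[b]]:
                    links += 1
        ccs.append(2.0 * links / (k * (k - 1)))
    return sum(ccs) / n, ccs


def oracle_floyd_warshall(adj):
    n = len(adj)
    d = [[0.0 if i == j else (1.0 if adj[i][j] else float("inf"))
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def oracle_cpl(adj):
    """Reachable-pairs CPL; isolated/unreachable nodes contribute 0."""
    d = oracle_floyd_warshall(adj)
    n = len(adj)
    if sum(sum(row) for row in adj) == 0:
        return float("nan")
    per_node = []
    for i in range(n):
        dists = [d[i][j] for j in range(n) if j != i and np.isfinite(d[i][j])]
        per_node.append(sum(dists) / len(dists) if dists else 0.0)
    return sum(per_node) / n


def graph_from_adj(adj):
    adj = np.asarray(adj, dtype=bool)
    labels = tuple(f"n{i}" for i in range(len(adj)))
    return BinaryGraph(adj, labels, threshold_used=0.0)


def random_graph(rng, n, p):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return (a | a.T)


def matrix_from_values(values):
    values = np.asarray(values, dtype=np.float64)
    np.fill_diagonal(values, 1.0)
    labels = tuple(f"n{i}" for i in range(len(values)))
    return ConnectivityMatrix(values, labels, "delta", "pre", "s0", 100)


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_hand_built_cut(self):
        v = np.array([[1.0, 0.9, 0.73],
                      [0.9, 1.0, 0.72],
                      [0.73, 0.72, 1.0]])
        g = binarize(matrix_from_values(v), fraction=0.8)
        assert g.threshold_used == pytest.approx(0.72)
        assert g.adjacency[0, 1]          # 0.9  > 0.72
        assert g.adjacency[0, 2]          # 0.73 > 0.72
        assert not g.adjacency[1, 2]      # 0.72 is a tie -> excluded

    def test_all_equal_gives_empty_at_full_fraction(self):
        # strict inequality at the cut: nothing exceeds its own maximum
        v = np.full((4, 4), 0.5)
        g = binarize(matrix_from_values(v), fraction=1.0)
        assert g.n_edges == 0

    def test_fraction_one_no_edges(self, rng):
        v = rng.uniform(0.1, 0.9, (5, 5))
        v = 0.5 * (v + v.T)
        g = binarize(matrix_from_values(v), fraction=1.0)
        assert g.n_edges == 0

    def test_fraction_bounds(self, rng):
        m = matrix_from_values(np.full((3, 3), 0.5))
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                binarize(m, fraction=bad)

    def test_zero_matrix_warns(self):
        m = matrix_from_values(np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            g = binarize(m)
        assert g.n_edges == 0

    def test_diagonal_excluded_from_max(self):
        # off-diagonal max 0.5 -> cut 0.4, not 0.8 from the unit diagonal
        v = np.full((3, 3), 0.5)
        g = binarize(matrix_from_values(v), fraction=0.8)
        assert g.threshold_used == pytest.approx(0.4)
        assert g.n_edges == 3

    def test_threshold_nesting(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 1, (8, 8))
            v = 0.5 * (v + v.T)
            m = matrix_from_values(v)
            high = binarize(m, 0.8).adjacency
            low = binarize(m, 0.6).adjacency
            assert np.all(low | ~high)  # high-threshold edges are a subset


class TestClusteringCoefficient:
    def test_complete_graph(self):
        adj = ~np.eye(5, dtype=bool)
        mean_cc, cc = clustering_coefficient(graph_from_adj(adj))
        assert mean_cc == pytest.approx(1.0)
        assert np.allclose(cc, 1.0)

    def test_star_graph(self):
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        mean_cc, _ = clustering_coefficient(graph_from_adj(adj))
        assert mean_cc == pytest.approx(0.0)

    def test_triangle_with_pendant(self):
        # triangle a-b-c plus pendant edge d-a: mean CC = 7/12
        adj = np.zeros((4, 4), dtype=bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (0, 3)]:
            adj[i, j] = adj[j, i] = True
        mean_cc, cc = clustering_coefficient(graph_from_adj(adj))
        assert mean_cc == pytest.approx(7 / 12)
        assert cc[0] == pytest.approx(1 / 3)
        assert cc[3] == 0.0

    def test_against_oracle_random(self, rng):
        for _ in range(50):
            adj = random_graph(rng, 8, rng.uniform(0.1, 0.9))
            mean_cc, cc = clustering_coefficient(graph_from_adj(adj))
            o_mean, o_cc = oracle_clustering(adj.tolist())
            assert mean_cc == pytest.approx(o_mean, abs=1e-12)
            assert np.allclose(cc, o_cc, atol=1e-12)


class TestShortestPaths:
    def test_path_graph(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        d = shortest_path_matrix(graph_from_adj(adj))
        assert d[0, 2] == 2.0

    def test_disconnected_infinite(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        d = shortest_path_matrix(graph_from_adj(adj))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        assert d[0, 1] == 1.0 and d[2, 3] == 1.0

    def test_against_floyd_warshall(self, rng):
        for _ in range(100):
            adj = random_graph(rng, 8, rng.uniform(0.05, 0.6))
            d = shortest_path_matrix(graph_from_adj(adj))
            assert np.array_equal(d, oracle_floyd_warshall(adj.tolist()))


class TestCharacteristicPathLength:
    def test_complete_graph(self):
        for n in (3, 5, 8):
            adj = ~np.eye(n, dtype=bool)
            assert characteristic_path_length(graph_from_adj(adj)) == (
                pytest.approx(1.0))

    def test_path_graph_hand_value(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        assert characteristic_path_length(graph_from_adj(adj)) == (
            pytest.approx(4 / 3))

    def test_empty_graph_nan_with_warning(self):
        g = graph_from_adj(np.zeros((4, 4), dtype=bool))
        with pytest.warns(UserWarning):
            assert np.isnan(characteristic_path_length(g))

    def test_isolated_nodes_warn(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        with pytest.warns(UserWarning):
            cpl = characteristic_path_length(graph_from_adj(adj))
        assert cpl == pytest.approx(2 / 3)  # (1 + 1 + 0) / 3

    def test_against_oracle_random(self, rng):
        for _ in range(50):
            adj = random_graph(rng, 7, rng.uniform(0.05, 0.8))
            g = graph_from_adj(adj)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cpl = characteristic_path_length(g)
            oracle = oracle_cpl(adj.tolist())
            if np.isnan(oracle):
                assert np.isnan(cpl)
            else:
                assert cpl == pytest.approx(oracle, abs=1e-12)


class TestNodeDegrees:
    def test_star(self):
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        deg = node_degrees(graph_from_adj(adj))
        assert deg[0] == 4 and np.all(deg[1:] == 1)

    def test_handshake_lemma(self, rng):
        for _ in range(100):
            adj = random_graph(rng, 10, rng.uniform(0, 1))
            g = graph_from_adj(adj)
            assert node_degrees(g).sum() == 2 * g.n_edges

    def test_complete_19(self):
        adj = ~np.eye(19, dtype=bool)
        assert np.all(node_degrees(graph_from_adj(adj)) == 18)


class TestPermutationEquivariance:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 21 - 1))
    def test_relabeling(self, bits):
        # 7-node graph from the bitmask; random-ish permutation from the bits
        n = 7
        adj = np.zeros((n, n), dtype=bool)
        iu = np.triu_indices(n, 1)
        for idx in range(len(iu[0])):
            if (bits >> idx) & 1:
                adj[iu[0][idx], iu[1][idx]] = adj[iu[1][idx], iu[0][idx]] = True
        perm = np.random.default_rng(bits).permutation(n)
        permuted = adj[np.ix_(perm, perm)]
        g1, g2 = graph_from_adj(adj), graph_from_adj(permuted)
        assert clustering_coefficient(g1)[0] == pytest.approx(
            clustering_coefficient(g2)[0], abs=1e-12)
        assert np.array_equal(node_degrees(g1)[perm], node_degrees(g2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = characteristic_path_length(g1)
            c2 = characteristic_path_length(g2)
        assert (np.isnan(c1) and np.isnan(c2)) or c1 == pytest.approx(c2)


def test_network_metrics_bundle(rng):
    adj = random_graph(rng, 6, 0.5)
    g = graph_from_adj(adj)
    nm = network_metrics(g)
    assert nm.n_nodes == 6
    assert nm.degrees.sum() == 2 * g.n_edges
    assert 0.0 <= nm.mean_cc <= 1.0
    assert nm.d_ij.shape == (6, 6)
    # triangle counts consistent with the clustering coefficients
    _, cc = clustering_coefficient(g)
    for i in range(6):
        k = nm.degrees[i]
        if k >= 2:
            assert cc[i] == pytest.approx(2 * nm.t_i[i] / (k * (k - 1)))


def test_graph_exports(tmp_path):
    adj = np.zeros((3, 3), dtype=bool)
    adj[0, 1] = adj[1, 0] = True
    g = BinaryGraph(adj, ("Cz", "Pz", "O1"), threshold_used=0.5)
    edge_path = tmp_path / "edges.tsv"
    write_edge_list(edge_path, g)
    assert edge_path.read_text() == "ch1\tch2\nCz\tPz\n"
    adj_path = tmp_path / "adj.csv"
    write_adjacency_csv(adj_path, g)
    lines = adj_path.read_text().strip().split("\n")
    assert lines[0] == ",Cz,Pz,O1"
    assert lines[1] == "Cz,0,1,0"


def test_self_loop_rejected():
    adj = np.eye(3, dtype=bool)
    with pytest.raises(ValueError):
        BinaryGraph(adj, ("a", "b", "c"), 0.1)
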