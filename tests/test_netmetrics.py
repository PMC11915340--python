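"""Graph metrics against independent oracles (networkx / brute force)."""

import networkx as nx
import numpy as np
import pytest

from qeegpred.netmetrics import (SPARSITIES, ThresholdedGraph, auc_over_sparsities,
                                 characteristic_path_length, clustering_coefficient,
                                 metric_curves, small_worldness,
                                 threshold_proportional)


def random_weighted_adjacency(n, density, rng):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.05, 1.0, len(iu[0])) * mask
    w[iu] = vals
    return w + w.T


def nx_cpl(adj):
    """networkx oracle: mean shortest 1/w path over the largest component."""
    g = nx.from_numpy_array(adj)
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    if sub.number_of_nodes() < 2:
        return float("nan")
    total, cnt = 0.0, 0
    lengths = dict(nx.all_pairs_dijkstra_path_length(sub, weight="length"))
    nodes = sorted(sub.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            total += lengths[u][v]
            cnt += 1
    return total / cnt


def nx_cc(adj):
    """networkx oracle: Onnela weighted clustering, averaged with 0 for deg<2."""
    g = nx.from_numpy_array(adj)
    c = nx.clustering(g, weight="weight")
    return float(np.mean([c[i] for i in g.nodes]))


def brute_force_cc(adj):
    """Direct triangle enumeration of the Onnela coefficient."""
    n = adj.shape[0]
    w = adj / adj.max()
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        t = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                if adj[j, h] > 0:
                    t += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
        cs.append(2 * t / (k * (k - 1)))
    return float(np.mean(cs))


class TestThreshold:
    def test_sparsity_point_one_keeps_17_of_171(self, rng):
        adj = random_weighted_adjacency(19, 1.0, rng)
        g = threshold_proportional(adj, 0.1)
        assert g.n_edges == 17

    def test_sparsity_one_is_identity(self, rng):
        adj = random_weighted_adjacency(19, 1.0, rng)
        g = threshold_proportional(adj, 1.0)
        np.testing.assert_array_equal(g.adjacency, adj)

    def test_retained_weights_unchanged(self, rng):
        adj = random_weighted_adjacency(19, 1.0, rng)
        g = threshold_proportional(adj, 0.3)
        kept = g.adjacency > 0
        np.testing.assert_array_equal(g.adjacency[kept], adj[kept])

    def test_all_equal_weights_tie_break_deterministic(self):
        adj = np.ones((19, 19)) - np.eye(19)
        a = threshold_proportional(adj, 0.5).adjacency
        b = threshold_proportional(adj, 0.5).adjacency
        np.testing.assert_array_equal(a, b)
        assert (a[np.triu_indices(19, 1)] > 0).sum() == 86  # round(0.5*171)

    def test_invalid_sparsity(self, rng):
        adj = random_weighted_adjacency(5, 1.0, rng)
        with pytest.raises(ValueError):
            threshold_proportional(adj, 0.0)


class TestCPL:
    def test_complete_unit_graph(self):
        adj = np.ones((10, 10)) - np.eye(10)
        assert characteristic_path_length(ThresholdedGraph(adj, 1.0)) == 1.0

    def test_three_node_path(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[1, 2] = adj[2, 1] = 1.0
        assert characteristic_path_length(ThresholdedGraph(adj, 1.0)) == pytest.approx(4 / 3)

    def test_oracle_equivalence_small_graphs(self, rng):
        for _ in range(100):
            n = rng.integers(4, 9)
            adj = random_weighted_adjacency(n, 0.6, rng)
            if not (adj > 0).any():
                continue
            ours = characteristic_path_length(ThresholdedGraph(adj, 1.0))
            np.testing.assert_allclose(ours, nx_cpl(adj), atol=1e-10)

    def test_oracle_equivalence_19_nodes(self, rng):
        for _ in range(10):
            adj = random_weighted_adjacency(19, 0.25, rng)
            ours = characteristic_path_length(ThresholdedGraph(adj, 1.0))
            np.testing.assert_allclose(ours, nx_cpl(adj), atol=1e-10)

    def test_empty_graph_flagged(self):
        assert np.isnan(characteristic_path_length(ThresholdedGraph(np.zeros((5, 5)), 1.0)))

    def test_monotone_nonincreasing_in_sparsity(self, rng):
        adj = random_weighted_adjacency(19, 1.0, rng)
        cpls = [characteristic_path_length(threshold_proportional(adj, s))
                for s in SPARSITIES]
        connected = [c for c in cpls if np.isfinite(c)]
        assert all(a >= b - 1e-12 for a, b in zip(connected, connected[1:]))

    def test_weight_scaling(self, rng):
        adj = random_weighted_adjacency(19, 0.4, rng)
        c1 = characteristic_path_length(ThresholdedGraph(adj, 1.0))
        c2 = characteristic_path_length(ThresholdedGraph(3.0 * adj, 1.0))
        assert c2 == pytest.approx(c1 / 3.0)


class TestCC:
    def test_unit_triangle(self):
        adj = np.ones((3, 3)) - np.eye(3)
        assert clustering_coefficient(ThresholdedGraph(adj, 1.0)) == pytest.approx(1.0)

    def test_star_graph_no_triangles(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 0.8
        assert clustering_coefficient(ThresholdedGraph(adj, 1.0)) == 0.0

    def test_oracle_equivalence(self, rng):
        for _ in range(100):
            n = rng.integers(4, 9)
            adj = random_weighted_adjacency(n, 0.6, rng)
            if not (adj > 0).any():
                continue
            ours = clustering_coefficient(ThresholdedGraph(adj, 1.0))
            np.testing.assert_allclose(ours, nx_cc(adj), atol=1e-10)
            np.testing.assert_allclose(ours, brute_force_cc(adj), atol=1e-10)

    def test_max_normalisation_makes_cc_scale_invariant(self, rng):
        adj = random_weighted_adjacency(19, 0.4, rng)
        a = clustering_coefficient(ThresholdedGraph(adj, 1.0))
        b = clustering_coefficient(ThresholdedGraph(5.0 * adj, 1.0))
        assert a == pytest.approx(b, abs=1e-12)


class TestSigma:
    def test_random_graph_sigma_near_one(self, rng):
        vals = []
        for seed in range(5):
            adj = random_weighted_adjacency(19, 0.5,
                                            np.random.default_rng(100 + seed))
            s, _, _ = small_worldness(ThresholdedGraph(adj, 1.0), n_null=100,
                                      seed=seed)
            vals.append(s)
        assert all(0.8 <= v <= 1.2 for v in vals)

    def test_watts_strogatz_lattice_is_small_world(self, rng):
        g = nx.watts_strogatz_graph(30, 6, 0.1, seed=1)
        adj = nx.to_numpy_array(g) * rng.uniform(0.5, 1.0, (30, 30))
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        s, gamma, lam = small_worldness(ThresholdedGraph(adj, 1.0), n_null=100,
                                        seed=0)
        assert s > 1.0
        assert gamma > 1.0

    def test_deterministic_under_seed(self, rng):
        adj = random_weighted_adjacency(19, 0.3, rng)
        g = ThresholdedGraph(adj, 1.0)
        a = small_worldness(g, n_null=100, seed=7)
        b = small_worldness(g, n_null=100, seed=7)
        assert a == b

    def test_nulls_preserve_degree_sequence(self, rng):
        from qeegpred.netmetrics import _rewire_edges

        adj = random_weighted_adjacency(19, 0.3, rng)
        iu = np.triu_indices(19, 1)
        mask = adj[iu] > 0
        edges = np.column_stack([iu[0][mask], iu[1][mask]])
        rewired = _rewire_edges(edges, 19, rng)
        deg = np.zeros(19, int)
        np.add.at(deg, edges.ravel(), 1)
        deg_r = np.zeros(19, int)
        np.add.at(deg_r, rewired.ravel(), 1)
        np.testing.assert_array_equal(deg, deg_r)
        assert not np.array_equal(np.sort(edges, 1), np.sort(rewired, 1))


class TestAUC:
    def test_constant_curve(self):
        assert auc_over_sparsities(np.full(9, 2.5)) == pytest.approx(2.5)

    def test_linear_ramp(self):
        assert auc_over_sparsities(np.linspace(1.0, 2.0, 9)) == pytest.approx(1.5)

    def test_matches_manual_trapezoid_oracle(self, rng):
        vals = rng.uniform(0.5, 3.0, 9)
        manual = sum(
            0.5 * (vals[i] + vals[i + 1]) * (SPARSITIES[i + 1] - SPARSITIES[i])
            for i in range(8)
        ) / (SPARSITIES[-1] - SPARSITIES[0])
        assert auc_over_sparsities(vals) == pytest.approx(manual, abs=1e-12)

    def test_missing_value_flags_summary(self):
        vals = np.full(9, 1.0)
        vals[3] = np.nan
        assert np.isnan(auc_over_sparsities(vals))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            auc_over_sparsities(np.ones(5))


class TestCohortDirection:
    def test_lattice_coupling_gives_longer_cpl_than_random(self):
        """Lattice-like strong edges vs random strong edges on a noise floor:
        the lattice group shows longer CPL in >= 90% of replicates."""
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            floor = random_weighted_adjacency(19, 1.0, rng) * 0.3

            lattice = floor.copy()
            for i in range(19):
                j = (i + 1) % 19
                lattice[i, j] = lattice[j, i] = 0.9 + 0.05 * rng.random()

            randg = floor.copy()
            iu = np.triu_indices(19, 1)
            sel = rng.choice(171, 19, replace=False)
            randg[iu[0][sel], iu[1][sel]] = 0.9 + 0.05 * rng.random(19)
            randg[iu[1][sel], iu[0][sel]] = randg[iu[0][sel], iu[1][sel]]

            cpl_l = metric_curves(lattice, n_null=0, seed=rep)["CPL"].auc_value
            cpl_r = metric_curves(randg, n_null=0, seed=rep)["CPL"].auc_value
            wins += cpl_l > cpl_r
        assert wins >= 0.9 * n_rep


def test_metric_curves_structure(rng):
    adj = random_weighted_adjacency(19, 0.8, rng)
    curves = metric_curves(adj, band="alpha", n_null=10, seed=0)
    for name in ("CPL", "CC", "Sigma"):
        c = curves[name]
        assert len(c.values) == 9
        if np.isfinite(c.auc_value):
            assert min(c.values) - 1e-12 <= c.auc_value <= max(c.values) + 1e-12
    assert curves["Sigma"].gamma is not None
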