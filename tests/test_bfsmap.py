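import networkx as nx
import numpy as np
import pytest

from netcurve import (bfs_map, configuration_model, curve_deviation,
                      efficiency_profile, empirical_curve, giant_component,
                      lattice, poisson_rg, rrg, rrg_curves,
                      tree_degree_distribution)


class TestReplayedTraversal:
    """Replay a fully worked 6-vertex traversal and check every coordinate."""

    def test_tree_coordinates(self, fig_graph, fig_order):
        m = bfs_map(fig_graph, root=2, neighbor_order=fig_order)
        # touch order: 2, 1, 3, 4, 5, 0
        np.testing.assert_array_equal(m.tree_x * 6, np.arange(1, 7))
        # second touched vertex has its parent at position 1/6,
        # fourth at 1/6, fifth at 2/6
        assert m.tree_y[1] * 6 == 1
        assert m.tree_y[3] * 6 == 1
        assert m.tree_y[4] * 6 == 2

    def test_graph_copy_coordinates(self, fig_graph, fig_order):
        m = bfs_map(fig_graph, root=2, neighbor_order=fig_order)
        pts = set(zip((m.graph_x * 6).astype(int).tolist(),
                      (m.graph_y * 6).astype(int).tolist()))
        # copies pushed while exploring the second explored vertex
        assert {(5, 2), (6, 2), (7, 2)} <= pts
        # the copy through which the bidirectional edge returns much later
        assert (12, 4) in pts

    def test_root_copy_first(self, fig_graph, fig_order):
        m = bfs_map(fig_graph, root=2, neighbor_order=fig_order)
        assert m.graph_x[0] * 6 == 1 and m.graph_y[0] == 0


class TestMappingInvariants:
    def test_counts_connected(self):
        g = rrg(500, 3, seed=0)
        m = bfs_map(g, seed=1)
        assert len(m.tree_x) == 500
        assert len(m.graph_x) == 2 * g.number_of_edges() + 1

    def test_parents_precede_children(self, rng):
        g = poisson_rg(2000, z=3.0, seed=2)
        m = bfs_map(g, seed=3)
        assert np.all(m.tree_y < m.tree_x)
        assert np.all(m.graph_y < m.graph_x)

    def test_monotone_point_clouds(self):
        g = rrg(1000, 4, seed=4)
        m = bfs_map(g, seed=5)
        assert np.all(np.diff(m.tree_y) >= 0)
        assert np.all(np.diff(m.graph_y) >= 0)

    def test_determinism(self):
        g = rrg(800, 3, seed=6)
        m1, m2 = bfs_map(g, seed=7), bfs_map(g, seed=7)
        np.testing.assert_array_equal(m1.tree_y, m2.tree_y)
        np.testing.assert_array_equal(m1.graph_y, m2.graph_y)
        assert m1.root == m2.root

    def test_self_loop_contributes_two_copies_no_touch(self):
        g = nx.MultiGraph([(0, 1), (1, 1)])
        m = bfs_map(g, root=0)
        assert len(m.graph_x) == 2 * 2 + 1
        assert len(m.tree_x) == 2

    def test_parallel_edges_one_copy_per_endpoint(self):
        g = nx.MultiGraph([(0, 1), (0, 1)])
        m = bfs_map(g, root=0)
        assert len(m.graph_x) == 5

    def test_root_outside_range_rejected(self):
        with pytest.raises(ValueError, match="root"):
            bfs_map(nx.path_graph(5), root=9)


class TestEmpiricalCurve:
    def test_graph_curve_endpoint_of_connected_graph(self):
        g = rrg(2000, 3, seed=8)
        c = empirical_curve(bfs_map(g, seed=9), "graph")
        assert c.S == 1.0
        assert c.x_end == pytest.approx((2 * g.number_of_edges() + 1) / 2000)

    def test_same_seed_identical_curves(self):
        g = poisson_rg(3000, z=2.5, seed=10)
        c1 = empirical_curve(bfs_map(g, seed=11), "graph")
        c2 = empirical_curve(bfs_map(g, seed=11), "graph")
        np.testing.assert_array_equal(c1.y, c2.y)

    def test_single_run_matches_analytic_tree_curve(self):
        n = 10_000
        g = rrg(n, 3, seed=12)
        m = bfs_map(g, seed=13)
        tree, _ = rrg_curves(3)
        dev = curve_deviation(m.tree_x, m.tree_y, tree)
        assert dev < 0.02

    def test_deviation_from_analytic_curve_shrinks_with_size(self):
        """Finite-size fluctuations around the mean-field curve decay in N."""
        import netcurve as ncv

        def median_dev(make, ana, sizes):
            out = []
            for n in sizes:
                devs = []
                for seed in range(3):
                    rng = np.random.default_rng(1000 * n + seed)
                    m = bfs_map(make(n, rng), seed=rng)
                    devs.append(curve_deviation(m.graph_x, m.graph_y, ana))
                out.append(np.median(devs))
            return out

        sizes = (1000, 10_000)
        cases = [
            (lambda n, rng: rrg(n, 3, seed=rng), rrg_curves(3)[1]),
            (lambda n, rng: poisson_rg(n, z=4.0, seed=rng),
             ncv.poisson_curves(4.0)[1]),
            (lambda n, rng: ncv.lerrg(1, n, 6, seed=rng),
             ncv.lerrg_curves(1, 6)[1]),
        ]
        for make, ana in cases:
            devs = median_dev(make, ana, sizes)
            assert devs[1] < devs[0]


class TestEfficiencyProfile:
    def test_eta_bounded(self):
        g = rrg(1000, 4, seed=14)
        prof = efficiency_profile(g, runs=3, seed=15)
        assert np.all(prof.eta >= 0) and np.all(prof.eta <= 1)
        assert np.all(prof.d_T <= prof.d_G + 1e-12)

    def test_rrg_eta_decreasing(self):
        # analytically eta(x) = (1-x)^{k-2} for the k-regular family
        g = rrg(5000, 4, seed=16)
        prof = efficiency_profile(g, runs=5, seed=17, grid_size=20)
        good = prof.counts > 0
        eta = prof.eta[good]
        assert np.all(np.diff(eta) < 0.05)  # decreasing up to binning noise
        x = prof.x[good]
        np.testing.assert_allclose(eta, (1 - x) ** 2, atol=0.08)

    def test_lattice_below_then_above_counterpart(self):
        from netcurve import random_counterpart
        g = lattice(2, 40)
        rngseed = 18
        p_lat = efficiency_profile(g, runs=10, seed=rngseed, grid_size=10)
        cp = nx.convert_node_labels_to_integers(random_counterpart(g, seed=19))
        p_cp = efficiency_profile(cp, runs=10, seed=rngseed, grid_size=10)
        assert p_lat.eta[0] < p_cp.eta[0]
        assert p_lat.eta[-2] > p_cp.eta[-2]


class TestTreeDegreeDistribution:
    def test_star_center(self):
        g = nx.star_graph(99)
        hist = tree_degree_distribution(g, runs=1, seed=20)
        assert hist[99] > 0  # the center harvests all 99 leaves

    def test_normalized(self):
        g = rrg(500, 3, seed=21)
        hist = tree_degree_distribution(g, runs=2, seed=22)
        assert hist.sum() == pytest.approx(1.0)


class TestGiantComponent:
    def test_connected(self):
        g = rrg(100, 3, seed=23)
        _, frac = giant_component(nx.Graph(g))
        assert frac == 1.0

    def test_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3))
        sub, frac = giant_component(g)
        assert frac == 5 / 8
        assert sub.number_of_nodes() == 5

    def test_er_fraction_matches_fixed_point(self):
        # oracle: S = 1 - u with u the fixed point of u = exp(z(u-1))
        z, n = 2.0, 100_000
        u = 0.5
        for _ in range(200):
            u = np.exp(z * (u - 1))
        S_oracle = 1 - u
        assert S_oracle == pytest.approx(0.7968, abs=1e-4)
        g = poisson_rg(n, z=z, seed=24)
        _, frac = giant_component(g)
        assert frac == pytest.approx(S_oracle, abs=0.01)
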