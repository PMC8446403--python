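import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cogchange import connectome as cn
from cogchange.connectome import _adjacency, _rewired_adjacency
from cogchange.datatypes import Connectome


def _conn(w, sid="s", tp="t1"):
    return Connectome(sid, tp, [f"r{i}" for i in range(w.shape[0])], w)


def _random_conn(rng, n=30, density=0.5):
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    w = w + w.T
    return _conn(w)


class TestNormalizeStrength:
    def test_constant_weights_become_one(self):
        w = np.full((10, 10), 3.7)
        np.fill_diagonal(w, 0)
        out = cn.normalize_strength(_conn(w))
        iu = np.triu_indices(10, 1)
        # constant matrix: every weight equals the mean weight
        np.testing.assert_allclose(out.weights[iu], 3.7 / np.mean(w[iu]))

    def test_scale_invariance(self, rng):
        conn = _random_conn(rng)
        doubled = conn.with_weights(conn.weights * 2)
        np.testing.assert_allclose(
            cn.normalize_strength(conn).weights,
            cn.normalize_strength(doubled).weights,
            atol=1e-12,
        )

    def test_mean_offdiagonal_weight_is_one(self, rng):
        out = cn.normalize_strength(_random_conn(rng))
        iu = np.triu_indices(out.n_nodes, 1)
        assert np.mean(out.weights[iu]) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cn.normalize_strength(_conn(np.zeros((5, 5))))


class TestThreshold:
    def test_edge_count_at_standard_density(self, rng):
        conn = _random_conn(rng, n=90, density=0.9)
        g = cn.threshold_to_density(conn, 0.06)
        assert g.number_of_edges() == 240  # round(0.06 * 90*89/2)

    def test_matches_sort_and_cut_oracle(self, rng):
        conn = _random_conn(rng, n=25, density=0.8)
        d = 0.2
        g = cn.threshold_to_density(conn, d)
        k = round(d * 25 * 24 / 2)
        iu = np.triu_indices(25, 1)
        weights = conn.weights[iu]
        cutoff = np.sort(weights)[::-1][k - 1]
        kept = {(int(i), int(j)) for i, j in zip(*np.triu_indices(25, 1))
                if conn.weights[i, j] > cutoff}
        assert kept <= set(map(tuple, map(sorted, g.edges())))
        assert g.number_of_edges() == k

    def test_sparse_matrix_keeps_all_edges_with_warning(self):
        w = np.zeros((20, 20))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 2.0
        with pytest.warns(UserWarning, match="nonzero"):
            g = cn.threshold_to_density(_conn(w), 0.5)
        assert g.number_of_edges() == 2
        assert g.graph["achieved_density"] == pytest.approx(2 / 190)

    def test_invalid_density(self, rng):
        with pytest.raises(ValueError):
            cn.threshold_to_density(_random_conn(rng), 1.5)


class TestClusteringAndPath:
    def test_complete_graph(self):
        c, l = cn.clustering_and_path(nx.complete_graph(5))
        assert c == 1.0 and l == 1.0

    def test_path_graph_hand_computation(self):
        c, l = cn.clustering_and_path(nx.path_graph(3))
        assert c == 0.0
        assert l == pytest.approx((1 + 1 + 2) / 3)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            cn.clustering_and_path(np.zeros((4, 4)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(25, 0.2, seed=seed)
        if g.number_of_edges() == 0:
            return
        c, l = cn.clustering_and_path(g)
        assert c == pytest.approx(nx.average_clustering(g), abs=1e-12)
        # networkx route for mean shortest path over reachable pairs
        tot, cnt = 0, 0
        for _, lengths in nx.all_pairs_shortest_path_length(g):
            for target, dist in lengths.items():
                if dist > 0:
                    tot += dist
                    cnt += 1
        assert l == pytest.approx(tot / cnt, abs=1e-12)


class TestRandomReference:
    def test_every_null_preserves_degree_sequence(self, rng):
        a = _adjacency(nx.gnp_random_graph(30, 0.2, seed=4))
        for s in range(10):
            null, accepted = _rewired_adjacency(a, 10 * int(a.sum() // 2), s)
            np.testing.assert_array_equal(null.sum(axis=0), a.sum(axis=0))
            assert not np.diag(null).any()
            np.testing.assert_array_equal(null, null.T)
            assert accepted > 0

    def test_same_seed_identical_means(self):
        g = nx.watts_strogatz_graph(40, 6, 0.1, seed=2)
        e1 = cn.random_reference(g, n_random=5, seed=42)
        e2 = cn.random_reference(g, n_random=5, seed=42)
        assert (e1.c_rand_mean, e1.l_rand_mean) == (e2.c_rand_mean, e2.l_rand_mean)

    def test_rewiring_destroys_lattice_clustering(self):
        """Ring-lattice clustering collapses under degree-preserving
        rewiring, so C_rand < C — the basis of small-world normalization."""
        g = nx.watts_strogatz_graph(60, 6, 0.0, seed=0)  # pure lattice
        c, _ = cn.clustering_and_path(g)
        below = sum(
            cn.random_reference(g, n_random=1, seed=s).c_rand_mean < c
            for s in range(20)
        )
        assert below >= 19

    def test_too_few_edges_rejected(self):
        g = nx.Graph([(0, 1)])
        g.add_nodes_from(range(4))
        with pytest.raises(ValueError):
            cn.random_reference(g)


class TestSmallWorldness:
    def test_unit_ratios(self):
        assert cn.small_worldness(0.3, 0.3, 2.0, 2.0) == (1.0, 1.0, 1.0)

    def test_hand_arithmetic(self):
        gamma, lam, sw = cn.small_worldness(0.5, 0.1, 2.2, 2.0)
        assert sw == pytest.approx(5 / 1.1)
        assert gamma == pytest.approx(5.0) and lam == pytest.approx(1.1)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            cn.small_worldness(0.0, 0.1, 2.0, 2.0)

    def test_watts_strogatz_graphs_are_small_world(self):
        """Rewired ring lattices at the atlas scale show SW > 1."""
        for seed in range(3):
            g = nx.watts_strogatz_graph(90, 10, 0.1, seed=seed)
            c, l = cn.clustering_and_path(g)
            null = cn.random_reference(g, n_random=5, seed=seed)
            _, _, sw = cn.small_worldness(c, null.c_rand_mean, l, null.l_rand_mean)
            assert sw > 1.0

    def test_composition_identity_every_density(self, rng):
        conn = _random_conn(rng, n=40, density=0.6)
        ms = cn.subject_metrics(conn, grid=cn.DensityGrid(0.08, 0.12, 0.02),
                                n_random=3, seed=1, nodal=False)
        np.testing.assert_allclose(
            ms.per_density["small_worldness"],
            ms.per_density["normalized_clustering"] / ms.per_density["normalized_path_length"],
            atol=1e-12,
        )


class TestEfficiencies:
    def test_complete_graph_k4(self):
        ge, le = cn.efficiencies(nx.complete_graph(4))
        assert ge == 1.0 and le == 1.0

    def test_edgeless_graph(self):
        ge, le = cn.efficiencies(np.zeros((5, 5)))
        assert ge == 0.0 and le == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_networkx(self, seed):
        g = nx.gnp_random_graph(20, 0.25, seed=seed)
        ge, le = cn.efficiencies(g)
        assert ge == pytest.approx(nx.global_efficiency(g), abs=1e-12)
        assert le == pytest.approx(nx.local_efficiency(g), abs=1e-12)


class TestNodeMetrics:
    def test_regular_graph_unit_normalized_degree(self):
        nd, _ = cn.node_metrics(nx.cycle_graph(10))
        np.testing.assert_allclose(nd, 1.0)

    def test_star_graph_betweenness(self):
        nd, bt = cn.node_metrics(nx.star_graph(5))  # node 0 is the hub
        assert bt[0] == pytest.approx(1.0)
        np.testing.assert_allclose(bt[1:], 0.0)
        assert nd[0] == pytest.approx(5 / (10 / 6))


class TestAUC:
    GRID = cn.DensityGrid(0.06, 0.12, 0.01)

    def test_constant_metric_rectangle(self):
        vals = np.full(7, 2.5)
        assert cn.auc_over_densities(vals, self.GRID) == pytest.approx(2.5 * 0.06 * 100)

    def test_linear_metric_exact(self):
        d = self.GRID.densities
        vals = 3.0 * d + 1.0
        exact = (1.5 * (0.12**2 - 0.06**2) + (0.12 - 0.06)) * 100
        assert cn.auc_over_densities(vals, self.GRID) == pytest.approx(exact)

    def test_matches_manual_trapezoid(self, rng):
        d = self.GRID.densities
        vals = rng.random(7)
        manual = sum(
            (vals[i] + vals[i + 1]) / 2 * (d[i + 1] - d[i]) for i in range(6)
        ) * 100
        assert cn.auc_over_densities(vals, self.GRID) == pytest.approx(manual, rel=1e-12)

    def test_missing_density_rejected(self):
        with pytest.raises(ValueError):
            cn.auc_over_densities(np.ones(5), self.GRID)
        with pytest.raises(ValueError):
            cn.auc_over_densities(np.r_[np.ones(6), np.nan], self.GRID)


class TestGroupAnalysis:
    def _frame(self, rng, node_effect=0.0, n_per_group=15, nodes=8):
        rows = []
        for gi, group in enumerate(["patient", "control"]):
            for s in range(n_per_group):
                sid = f"{group}{s}"
                for node in range(nodes):
                    base = rng.normal(10, 1)
                    delta = rng.normal(0, 0.5)
                    if node == 3 and group == "control":
                        delta += node_effect
                    for tp, v in (("t1", base), ("t2", base + delta)):
                        rows.append({"subject_id": sid, "group": group,
                                     "timepoint": tp, "metric": "node_degree_normalized",
                                     "node": f"r{node}", "value": v})
        return pd.DataFrame(rows)

    def test_identical_trajectories_null(self, rng):
        df = self._frame(rng, node_effect=0.0)
        out = cn.network_group_analysis(df)
        assert (out["p"] > 0.001).all()

    def test_designed_node_change_flagged_after_fdr(self, rng):
        df = self._frame(rng, node_effect=2.0)
        out = cn.network_group_analysis(df)
        sig = out[out["p_fdr"] < 0.01]["node"].tolist()
        assert sig == ["r3"]
        # delta direction: controls rose on the affected node
        row = out[out["node"] == "r3"].iloc[0]
        assert row["delta_mean_control"] > row["delta_mean_patient"]

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=90)
        # direct implementation of the BH step-up rule
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            prev = min(prev, p[idx] * m / rank)
            adj[idx] = prev
        np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_subject_missing_timepoint_excluded(self, rng):
        df = self._frame(rng)
        df = df[~((df.subject_id == "patient0") & (df.timepoint == "t2"))]
        out = cn.network_group_analysis(df)
        assert not out.empty
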