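"""Spearman network construction, MCL modules and module features."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from celldrop.io import log_transform
from celldrop.network import (
    build_network,
    mcl_cluster,
    module_features,
    network_stats,
    spearman_with_p,
)

from conftest import make_matrix


def brute_force_edges(values, ids, scc, p_thr):
    """Reference edge set via scipy.stats.spearmanr on every pair."""
    edges = {}
    p_mol = values.shape[1]
    for i in range(p_mol):
        for j in range(i + 1, p_mol):
            if np.std(values[:, i]) == 0 or np.std(values[:, j]) == 0:
                continue
            rho, p = stats.spearmanr(values[:, i], values[:, j])
            if abs(rho) > scc and p < p_thr:
                edges[(ids[i], ids[j])] = rho
    return edges


class TestSpearman:
    def test_monotone_increasing(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        rho, p = spearman_with_p(x, np.exp(x))
        assert rho == 1.0 and p == 0.0

    def test_monotone_decreasing(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        rho, _ = spearman_with_p(x, -(x**3))
        assert rho == -1.0

    def test_hand_ranked_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, p = spearman_with_p(x, y)
        assert rho == pytest.approx(0.8)  # 1 − 6·4/(5·24)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho)
        assert p == pytest.approx(ref_p, rel=1e-9)

    def test_constant_input_undefined(self):
        rho, p = spearman_with_p(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)


class TestBuildNetwork:
    def test_edge_rule(self):
        # three molecules engineered so pairwise rho are (strong+, weak, strong−)
        n = 30
        rng = np.random.default_rng(0)
        a = rng.normal(size=n)
        b = a + rng.normal(0, 0.3, n)          # strong positive with a
        c = -a + rng.normal(0, 0.3, n)         # strong negative with a
        vals = np.column_stack([a, b, c]) + 10
        m = make_matrix(vals, log=True)
        net = build_network(m, scc_threshold=0.6)
        assert net.has_edge("g0", "g1") and net.has_edge("g0", "g2")
        w01 = net["g0"]["g1"]
        assert w01["weight"] == pytest.approx(abs(w01["rho"]))
        assert net["g0"]["g2"]["rho"] < 0

    def test_exact_threshold_excluded(self):
        # permutation with Σd² = 12 at n = 5 gives rho = 0.4 exactly
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 4.0, 5.0, 2.0])
        rho, _ = spearman_with_p(x, y)
        assert rho == pytest.approx(0.4)
        m = make_matrix(np.column_stack([x, y]), log=True)
        net = build_network(m, scc_threshold=0.4, p_threshold=1.0)
        assert net.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(0, 1, size=(30, 12))
        m = make_matrix(vals, log=True)
        net = build_network(m, 0.3, 0.05)
        ref = brute_force_edges(vals, m.molecule_ids, 0.3, 0.05)
        assert {tuple(sorted(e)) for e in net.edges} == {
            tuple(sorted(e)) for e in ref
        }
        for (u, v), rho in ref.items():
            assert net[u][v]["rho"] == pytest.approx(rho)

    def test_isolated_molecules_dropped(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        vals = np.column_stack([a, a + rng.normal(0, 0.1, 40), rng.normal(size=40)]) + 20
        net = build_network(make_matrix(vals, log=True), 0.8, 0.05)
        assert "g2" not in net.nodes

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(0, 1, size=(25, 8))
        net_raw = build_network(make_matrix(vals, log=True), 0.4, 0.05)
        net_log = build_network(make_matrix(np.log2(vals + 1), log=True), 0.4, 0.05)
        assert set(net_raw.edges) == set(net_log.edges)


class TestNetworkStats:
    def test_star(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, str)
        nx.set_edge_attributes(g, 0.5, "rho")
        nx.set_edge_attributes(g, 0.5, "weight")
        s = network_stats(g)
        assert s["degrees"]["0"] == 5
        assert s["hubs"][0] == ("0", 5)

    def test_edge_signs(self):
        g = nx.Graph()
        for u, v, rho in [("a", "b", 0.5), ("b", "c", -0.6), ("c", "d", 0.7)]:
            g.add_edge(u, v, rho=rho, weight=abs(rho))
        s = network_stats(g)
        assert s["n_positive"] == 2 and s["n_negative"] == 1
        assert s["max_abs_rho"] == pytest.approx(0.7)


def weighted_clique(nodes, w=0.9):
    g = nx.Graph()
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            g.add_edge(u, v, rho=w, weight=w)
    return g


class TestMCL:
    def test_disconnected_triangles_are_modules(self):
        g = nx.compose(weighted_clique(["a", "b", "c"]), weighted_clique(["x", "y", "z"]))
        mods = mcl_cluster(g)
        assert sorted(sorted(m) for m in mods) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_singleton_node(self):
        g = weighted_clique(["a", "b", "c"])
        g.add_node("lonely")
        mods = mcl_cluster(g)
        assert {"lonely"} in mods

    def test_barbell_splits_at_weak_bridge(self):
        g = nx.compose(
            weighted_clique(["a", "b", "c", "d"], 0.9),
            weighted_clique(["w", "x", "y", "z"], 0.9),
        )
        g.add_edge("d", "w", rho=0.41, weight=0.41)
        mods = mcl_cluster(g, inflation=2.5)
        assert sorted(sorted(m) for m in mods) == [
            ["a", "b", "c", "d"],
            ["w", "x", "y", "z"],
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(25, 0.15, seed=int(seed))
        g = nx.relabel_nodes(g, str)
        for u, v in g.edges:
            w = float(rng.uniform(0.4, 1.0))
            g[u][v].update(rho=w, weight=w)
        mods = mcl_cluster(g)
        all_members = [n for mod in mods for n in mod]
        assert sorted(all_members) == sorted(g.nodes)  # disjoint and covering
        assert len(all_members) == len(set(all_members))

    def test_never_merges_components(self):
        rng = np.random.default_rng(10)
        g1 = nx.gnp_random_graph(10, 0.5, seed=1)
        g2 = nx.gnp_random_graph(10, 0.5, seed=2)
        g2 = nx.relabel_nodes(g2, lambda n: n + 100)
        g = nx.compose(nx.relabel_nodes(g1, str), nx.relabel_nodes(g2, str))
        for u, v in g.edges:
            w = float(rng.uniform(0.4, 1.0))
            g[u][v].update(rho=w, weight=w)
        comp1 = {str(n) for n in range(10)}
        for mod in mcl_cluster(g):
            assert mod <= comp1 or not (mod & comp1)

    def test_modules_ordered_by_size(self):
        g = nx.compose(weighted_clique(list("abcde")), weighted_clique(["x", "y"]))
        mods = mcl_cluster(g)
        assert [len(m) for m in mods] == sorted([len(m) for m in mods], reverse=True)


class TestModuleFeatures:
    def test_mean_of_members(self):
        m = make_matrix([[2.0, 4.0, 9.0]], log=True)
        f = module_features(m, [{"g0", "g1"}])
        assert f.values[0, 0] == pytest.approx(3.0)

    def test_singleton_module_equals_expression(self):
        vals = np.arange(6.0).reshape(3, 2)
        m = make_matrix(vals, log=True)
        f = module_features(m, [{"g1"}])
        np.testing.assert_allclose(f.values[:, 0], vals[:, 1])

    def test_singleton_partition_reproduces_matrix(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 5, (4, 6))
        m = make_matrix(vals, log=True)
        f = module_features(m, [{g} for g in m.molecule_ids])
        np.testing.assert_allclose(f.values, vals)

    def test_empty_module_rejected(self):
        m = make_matrix([[1.0]], log=True)
        with pytest.raises(ValueError, match="empty"):
            module_features(m, [set()])
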