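import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from miresponse.io import InteractionTable
from miresponse.topology import (
    ModulePartition,
    betweenness,
    closeness,
    edge_betweenness,
    enrich_modules,
    filter_by_median_score,
    mcl,
    read_gmt,
    select_hubs,
    topology_report,
)

from oracles import brute_betweenness, brute_closeness, brute_edge_betweenness


def _random_connected_graph(rng, n):
    while True:
        g = nx.gnp_random_graph(n, rng.uniform(0.3, 0.8), seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() >= n - 1:
            return g


class TestMedianFilter:
    def _table(self, rows):
        return InteractionTable(pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "combined_score"]))

    def test_strictly_above_median_kept(self):
        t = self._table([("a", "b", 1.0), ("b", "c", 2.0),
                         ("c", "d", 3.0), ("d", "a", 4.0)])
        g = filter_by_median_score(t, {"a", "b", "c", "d"})
        kept = {d["combined_score"] for _, _, d in g.edges(data=True)}
        assert kept == {3.0, 4.0}

    def test_all_scores_equal_keeps_nothing(self):
        t = self._table([("a", "b", 0.5), ("b", "c", 0.5), ("c", "a", 0.5)])
        with pytest.warns(UserWarning):
            g = filter_by_median_score(t, {"a", "b", "c"})
        assert g.number_of_edges() == 0

    def test_median_computed_before_de_restriction(self):
        # only one gene pair is DE, but the median uses all four scores
        t = self._table([("a", "b", 1.0), ("b", "c", 2.0),
                         ("c", "d", 3.0), ("d", "a", 4.0)])
        g = filter_by_median_score(t, {"c", "d"})
        assert set(g.edges()) == {("c", "d")}


class TestCentralities:
    def test_path_graph_hand_values(self):
        g = nx.path_graph(["A", "B", "C"])
        b = betweenness(g)
        assert b == {"A": 0.0, "B": 1.0, "C": 0.0}
        c = closeness(g)
        assert c["B"] == pytest.approx(1 / 2)
        assert c["A"] == pytest.approx(1 / 3)

    def test_star_center_is_maximal(self):
        g = nx.star_graph(3)  # center 0, three leaves
        b = betweenness(g)
        assert b[0] == pytest.approx(1.0)
        assert all(b[l] == 0.0 for l in (1, 2, 3))

    def test_complete_graph_zero_betweenness_equal_closeness(self):
        g = nx.complete_graph(4)
        assert all(v == 0.0 for v in betweenness(g).values())
        assert all(c == pytest.approx(1 / 3) for c in closeness(g).values())

    def test_single_edge_closeness(self):
        g = nx.Graph([("a", "b")])
        assert closeness(g) == {"a": 1.0, "b": 1.0}

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("lone")
        assert closeness(g)["lone"] == 0.0

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            betweenness(nx.Graph([("a", "b")]))

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            g = _random_connected_graph(rng, int(rng.integers(4, 9)))
            b = betweenness(g)
            bo = brute_betweenness(g.nodes(), g.edges())
            for v in g.nodes():
                assert b[v] == pytest.approx(bo[v], abs=1e-9)
            c = closeness(g)
            co = brute_closeness(g.nodes(), g.edges())
            for v in g.nodes():
                assert c[v] == pytest.approx(co[v], abs=1e-9)

    def test_relabeling_permutes_feature_values(self):
        g = _random_connected_graph(np.random.default_rng(7), 7)
        mapping = {v: f"n{v}" for v in g.nodes()}
        g2 = nx.relabel_nodes(g, mapping)
        b1, b2 = betweenness(g), betweenness(g2)
        for v in g.nodes():
            assert b1[v] == pytest.approx(b2[mapping[v]], abs=1e-12)


class TestEdgeBetweenness:
    def test_path_edge_scores(self):
        ranked = dict(edge_betweenness(nx.path_graph(["A", "B", "C"])))
        assert ranked[("A", "B")] == pytest.approx(2.0)
        assert ranked[("B", "C")] == pytest.approx(2.0)

    def test_triangle_symmetry(self):
        ranked = edge_betweenness(nx.complete_graph(3))
        assert all(s == pytest.approx(1.0) for _, s in ranked)

    def test_bridge_strictly_maximal_on_twin_cliques(self):
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                          ("b1", "b2"), ("b1", "b3"), ("b2", "b3"),
                          ("a1", "b1")])
        ranked = edge_betweenness(g)
        assert ranked[0][0] == ("a1", "b1")
        assert ranked[0][1] == pytest.approx(9.0)
        assert ranked[0][1] > ranked[1][1]

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            g = _random_connected_graph(rng, int(rng.integers(4, 9)))
            got = dict(edge_betweenness(g))
            exp = brute_edge_betweenness(g.nodes(), g.edges())
            for e, s in exp.items():
                assert got[e] == pytest.approx(s, abs=1e-9)


class TestHubs:
    def test_star_center_is_the_only_hub(self):
        report = topology_report(nx.star_graph(3))
        assert select_hubs(report) == [0]

    def test_regular_graph_has_no_hubs(self):
        report = topology_report(nx.cycle_graph(6))
        assert select_hubs(report) == []

    def test_hubs_have_above_median_degree(self):
        g = _random_connected_graph(np.random.default_rng(17), 8)
        report = topology_report(g)
        med = report.medians["degree"]
        for h in select_hubs(report):
            assert report.nodes.loc[h, "degree"] > med


class TestMCL:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = mcl(g)
        assert part.converged
        assert sorted(part.module_sizes.values()) == [3, 3]
        mods = part.modules()
        assert {frozenset(m) for m in mods.values()} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_bridged_twin_cliques_split_in_two(self):
        g = nx.Graph([("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                      ("b1", "b2"), ("b1", "b3"), ("b2", "b3"),
                      ("a1", "b1")])
        part = mcl(g, inflation=2.0)
        mods = {frozenset(m) for m in part.modules().values()}
        assert mods == {frozenset({"a1", "a2", "a3"}),
                        frozenset({"b1", "b2", "b3"})}

    def test_partition_is_a_valid_cover(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = _random_connected_graph(rng, int(rng.integers(4, 10)))
            part = mcl(g)
            assert sorted(part.membership) == sorted(g.nodes())
            assert sum(part.module_sizes.values()) == g.number_of_nodes()
            assert all(s > 0 for s in part.module_sizes.values())

    def test_invalid_parameters_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            mcl(g, inflation=1.0)
        with pytest.raises(ValueError):
            mcl(nx.Graph())


class TestEnrichment:
    def _partition(self, mapping):
        return ModulePartition(membership=mapping, iterations=1, converged=True)

    def test_hand_hypergeometric(self):
        # N=10, K=5, m=3, k=3 -> C(5,3)/C(10,3) = 10/120
        part = self._partition({f"g{i}": 1 for i in range(3)})
        universe = {f"g{i}" for i in range(10)}
        sets = {"S": {"g0", "g1", "g2", "g3", "g4"}}
        df = enrich_modules(part, sets, universe)
        assert df.iloc[0]["p_value"] == pytest.approx(10 / 120)

    def test_zero_overlap_gives_p_one(self):
        part = self._partition({"g0": 1, "g1": 1})
        df = enrich_modules(part, {"S": {"g8", "g9"}},
                            {f"g{i}" for i in range(10)})
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_module_equals_universe_gives_p_one(self):
        universe = {"g0", "g1", "g2"}
        part = self._partition({g: 1 for g in universe})
        df = enrich_modules(part, {"S": {"g0"}, "T": {"g1", "g2"}}, universe)
        assert np.allclose(df["p_value"], 1.0)

    def test_disjoint_set_skipped_with_warning(self):
        part = self._partition({"g0": 1})
        with pytest.warns(UserWarning):
            df = enrich_modules(part, {"S": {"zz"}}, {"g0", "g1"})
        assert len(df) == 0

    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("PI3K\tdesc\tg1\tg2\tg3\nIGF\tdesc\tg4\n")
        sets = read_gmt(p)
        assert sets == {"PI3K": {"g1", "g2", "g3"}, "IGF": {"g4"}}
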