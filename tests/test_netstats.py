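"""Network statistics: metrics, path profiles, randomization, group tests."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coppilink import netstats as ns
from coppilink.genesets import GeneSet
from conftest import toy_coppi


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Independent oracle: enumerate every shortest path explicitly."""
    out = {v: 0.0 for v in graph}
    for s, t in itertools.combinations(sorted(graph), 2):
        if not nx.has_path(graph, s, t):
            continue
        for path in nx.all_shortest_paths(graph, s, t):
            for v in path[1:-1]:
                out[v] += 1
    return out


class TestNodeMetrics:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        m = ns.node_metrics(g)
        assert m.loc["B", "betweenness"] == 1.0
        assert m.loc["A", "betweenness"] == 0.0
        assert m["degree"].tolist() == [1, 2, 1]

    def test_star_center(self):
        g = nx.star_graph(4)  # center 0, four leaves: C(4,2) = 6 paths
        m = ns.node_metrics(g)
        assert m.loc[0, "betweenness"] == 6.0

    def test_complete_graph_all_zero(self):
        m = ns.node_metrics(nx.complete_graph(5))
        assert (m["betweenness"] == 0.0).all()

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(
                n, float(rng.uniform(0.3, 0.9)), seed=trial
            )
            got = ns.path_count_betweenness(g)
            want = brute_force_betweenness(g)
            for v in g:
                assert got[v] == pytest.approx(want[v], abs=1e-9)

    def test_multiplicity_counted_not_fractional(self):
        # square with a diagonal detour: two shortest 2-paths between
        # opposite corners; the raw count credits each intermediate node 1
        g = nx.cycle_graph(4)  # 0-1-2-3-0
        got = ns.path_count_betweenness(g)
        # pair (0,2): shortest paths 0-1-2 and 0-3-2 -> nodes 1 and 3 get 1
        assert got[1] == 1.0 and got[3] == 1.0

    def test_log_betweenness_finite_for_leaves(self):
        m = ns.node_metrics(nx.star_graph(3))
        assert np.isfinite(m["log_betweenness"]).all()
        assert m.loc[1, "log_betweenness"] == 0.0


class TestShortestPathProfile:
    def test_single_edge_pair(self):
        g = nx.Graph([("x", "y")])
        prof = ns.shortest_path_profile({"x"}, {"y"}, g)
        assert prof.loc[0, "length"] == 1
        assert prof.loc[0, "proportion"] == 1.0

    def test_p4_within_set_multiset(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        nodes = set(g.nodes)
        prof = ns.shortest_path_profile(nodes, nodes, g).set_index("length")
        assert prof["n_pairs"].to_dict() == {1: 3, 2: 2, 3: 1}

    def test_toy_cross_profile_by_hand(self):
        g = nx.Graph(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "f"),
             ("f", "g")]
        )
        prof = ns.shortest_path_profile(
            {"a", "f"}, {"c", "e"}, g
        ).set_index("length")
        # a-c:2, a-e:4, f-c:2, f-e:4 (hand BFS)
        assert prof["n_pairs"].to_dict() == {2: 2, 4: 2}

    def test_unreachable_bin(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        prof = ns.shortest_path_profile({"a"}, {"d"}, g)
        assert prof.loc[0, "length"] == "unreachable"

    def test_overlapping_cross_sets_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError, match="disjoint"):
            ns.shortest_path_profile({"a", "b"}, {"b", "c"}, g)


@pytest.fixture(scope="module")
def scale_free_graph():
    return nx.barabasi_albert_graph(300, 4, seed=5)


class TestEmpiricalP:
    def test_extreme_set_small_p(self, scale_free_graph):
        g = scale_free_graph
        top = sorted(g.nodes, key=lambda v: (-g.degree(v), v))[:20]
        res = ns.empirical_p(
            ns.mean_degree, top, g, n_draws=500, matching="plain",
            rng_seed=1,
        )
        assert res.p <= 1 / 500

    def test_degree_matching_absorbs_degree_signal(self, scale_free_graph):
        # a degree-biased set (mostly drawn from the top quartile) looks
        # extreme under plain resampling but unremarkable once the draws
        # match its quartile composition — the conditional reversal of the
        # within-set interaction signal
        g = scale_free_graph
        rng = np.random.default_rng(5)
        quartiles = ns.degree_quartiles(g)
        observed = [
            *rng.choice(sorted(quartiles[3]), size=15, replace=False),
            *rng.choice(sorted(quartiles[2]), size=5, replace=False),
        ]
        plain = ns.empirical_p(
            ns.mean_degree, observed, g, n_draws=500, matching="plain",
            rng_seed=1,
        )
        matched = ns.empirical_p(
            ns.mean_degree, observed, g, n_draws=500,
            matching="degree_quartile", rng_seed=1,
        )
        assert plain.p < 0.05
        assert matched.p > 0.05

    def test_quartile_composition_exact_every_draw(self, scale_free_graph):
        g = scale_free_graph
        rng = np.random.default_rng(3)
        quartiles = ns.degree_quartiles(g)
        qsets = [set(q) for q in quartiles]
        observed = list(rng.choice(sorted(g.nodes), size=30, replace=False))
        counts = [sum(1 for v in observed if v in qs) for qs in qsets]
        for _ in range(200):
            pick = ns.degree_matched_sample(quartiles, counts, rng)
            got = [sum(1 for v in pick if v in qs) for qs in qsets]
            assert got == counts
            assert len(set(pick)) == len(observed)

    def test_planted_clique_edge_count_significant(self):
        rng = np.random.default_rng(7)
        g = nx.gnm_random_graph(150, 500, seed=2)
        clique = list(rng.choice(150, size=10, replace=False))
        g.add_edges_from(itertools.combinations(clique, 2))
        res = ns.empirical_p(
            ns.within_set_edge_count, clique, g, n_draws=1000,
            matching="plain", rng_seed=4,
        )
        assert res.p < 0.01

    def test_p_exact_proportion_no_smoothing(self, scale_free_graph):
        g = scale_free_graph
        members = sorted(g.nodes)[:15]
        res = ns.empirical_p(
            ns.mean_degree, members, g, n_draws=200, rng_seed=0
        )
        assert res.p == np.mean(res.null >= res.observed)
        assert 0.0 <= res.p <= 1.0
        assert len(res.null) == 200

    def test_pair_stat_cross_edges(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        assert ns.cross_edge_count(["a", "c"], ["b", "d"], g) == 4.0
        res = ns.empirical_p_pair(
            ns.cross_edge_count, ["a"], ["b"], g, n_draws=50, rng_seed=0
        )
        assert 0.0 <= res.p <= 1.0


class TestGroupComparison:
    def _metrics(self, values):
        return pd.DataFrame(
            {"degree": values},
            index=[f"g{i}" for i in range(len(values))],
        )

    def test_identical_distributions_p_one(self):
        m = self._metrics([1, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        gs_ = GeneSet("X", frozenset([f"g{i}" for i in range(5)]))
        res = ns.group_comparison(m, [gs_], metric_cols=("degree",))
        assert res["p"].iloc[0] > 0.99

    def test_rank_sum_matches_hand_u_statistic(self):
        # set {8,9,7}, others {1,2,3,4}: every set value beats every other
        # value -> U = 12, the maximum
        m = self._metrics([8, 9, 7, 1, 2, 3, 4])
        gs_ = GeneSet("X", frozenset(["g0", "g1", "g2"]))
        res = ns.group_comparison(m, [gs_], metric_cols=("degree",))
        assert res["statistic"].iloc[0] == 12.0

    def test_planted_high_degree_set_significant(self, scale_free_graph):
        g = scale_free_graph
        metrics = ns.node_metrics(g, betweenness=False)
        top = frozenset(
            sorted(g.nodes, key=lambda v: (-g.degree(v), v))[:25]
        )
        res = ns.group_comparison(
            metrics, [GeneSet("hub", top)], metric_cols=("degree",)
        )
        assert res["p"].iloc[0] < 0.01


class TestEdgeCoexpressionTests:
    def test_planted_high_weight_group(self):
        rng = np.random.default_rng(5)
        edges = []
        group_nodes = [f"m{i}" for i in range(6)]
        for u, v in itertools.combinations(group_nodes, 2):
            edges.append((u, v, rng.uniform(0.7, 0.95)))
        for i in range(40):
            edges.append((f"x{i}", f"y{i}", rng.uniform(0.0, 0.3)))
        cop = toy_coppi(edges)
        dnm = GeneSet("DNM", frozenset(group_nodes))
        cv = GeneSet("CV", frozenset(f"x{i}" for i in range(3)))
        res = ns.edge_coexpression_tests({"s": cop}, dnm, cv)
        row = res.set_index("group").loc["within_DNM"]
        assert row["mean_group"] > row["mean_other"]
        assert row["p_bonferroni"] < 0.001

    def test_group_covering_all_edges_reported_missing(self):
        cop = toy_coppi([("a", "b", 0.5), ("b", "c", 0.6)])
        res = ns.edge_group_coexpression_test(
            cop, {"all": ({"a", "b", "c"}, {"a", "b", "c"})}
        )
        assert np.isnan(res["p"].iloc[0])

    def test_null_weights_not_significant(self):
        rng = np.random.default_rng(9)
        edges = [
            (f"a{i}", f"b{i}", rng.uniform(0, 1)) for i in range(60)
        ]
        cop = toy_coppi(edges)
        dnm = GeneSet("DNM", frozenset(f"a{i}" for i in range(0, 20)))
        cv = GeneSet("CV", frozenset(f"b{i}" for i in range(20, 40)))
        res = ns.edge_coexpression_tests({"s": cop}, dnm, cv)
        ok = res["p_bonferroni"].dropna()
        assert (ok > 0.05).all()


class TestEmpiricalPCalibration:
    def test_null_uniformity_small(self, scale_free_graph):
        # reduced-size version of the KS calibration (full run in the
        # acceptance suite)
        from scipy import stats

        g = scale_free_graph
        metrics = ns.node_metrics(g)
        stat = ns.make_metric_stat(metrics, "log_betweenness")
        rng = np.random.default_rng(21)
        nodes = np.asarray(sorted(g.nodes))
        ps = []
        for i in range(60):
            observed = list(rng.choice(nodes, size=20, replace=False))
            res = ns.empirical_p(
                stat, observed, g, n_draws=200, rng_seed=1000 + i
            )
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
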