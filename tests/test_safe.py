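"""SAFE neighbourhood construction, permutation scoring, and ranking."""

import networkx as nx
import numpy as np
import pytest

from microstrat.io_metadata import ValidationError
from microstrat.mapper import Node, TDANetwork
from microstrat.safe import (
    NodeAttribute,
    enriched_nodes,
    neighborhoods,
    node_distances,
    node_values,
    rank_variables,
    safe_enriched_score,
    safe_scores,
    SAFEResult,
)
from tests.conftest import path_network


def make_network(edges, n_nodes) -> TDANetwork:
    nodes = {
        i: Node(members=frozenset({f"m{i}"}), bin_index=(i, 0), centroid=(0.0, 0.0))
        for i in range(n_nodes)
    }
    return TDANetwork(nodes=nodes, edges={tuple(sorted(e)) for e in edges}, params={})


def make_attr(network, values) -> NodeAttribute:
    return NodeAttribute(
        variable="v", node_ids=network.node_ids, values=np.asarray(values, float)
    )


class TestNodeValues:
    def test_dummy_mean(self):
        net = make_network([], 1)
        net.nodes[0] = Node(frozenset({"s1", "s2"}), (0, 0), (0.0, 0.0))
        attr = node_values(net, {"s1": 1.0, "s2": 0.0}, "dummy")
        assert attr.values[0] == 0.5

    def test_constant_passthrough(self):
        net = path_network(3)
        samples = {f"s{i}": 7.5 for i in range(5)}
        attr = node_values(net, samples, "const")
        np.testing.assert_array_equal(attr.values, 7.5)

    def test_missing_excluded_from_mean(self):
        net = make_network([], 1)
        net.nodes[0] = Node(frozenset({"a", "b", "c"}), (0, 0), (0.0, 0.0))
        attr = node_values(net, {"a": 1.0, "b": 3.0, "c": np.nan}, "x")
        assert attr.values[0] == 2.0

    def test_all_missing_node_flagged_zero(self):
        net = make_network([], 2)
        attr = node_values(net, {"m0": 4.0}, "x")
        assert attr.values[1] == 0.0
        assert attr.all_missing_nodes == [1]

    def test_fully_absent_variable_rejected(self):
        net = make_network([], 2)
        with pytest.raises(ValidationError):
            node_values(net, {"m0": np.nan}, "x")


class TestNodeDistances:
    def test_path_graph_hops(self):
        net = make_network([(0, 1), (1, 2)], 3)
        dist = node_distances(net)
        assert dist[0, 2] == 2
        assert dist[0, 1] == 1

    def test_disconnected_infinite(self):
        net = make_network([(0, 1)], 3)
        dist = node_distances(net)
        assert np.isinf(dist[0, 2])

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(8):
            n = int(rng.integers(5, 30))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 16)))
            net = make_network(list(g.edges()), n)
            dist = node_distances(net)
            for i in range(n):
                lengths = nx.single_source_shortest_path_length(g, i)
                for j in range(n):
                    expect = lengths.get(j, np.inf)
                    assert dist[i, j] == expect


class TestNeighborhoods:
    def test_path_graph_low_percentile(self):
        net = make_network([(0, 1), (1, 2)], 3)
        nbh = neighborhoods(net, percentile=0.5)
        assert nbh.threshold == 1
        assert nbh.as_sets()[0] == {0, 1}
        assert nbh.as_sets()[1] == {0, 1, 2}

    def test_complete_graph_everything(self):
        net = make_network([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)
        nbh = neighborhoods(net, percentile=50)
        assert all(s == {0, 1, 2, 3} for s in nbh.as_sets().values())

    def test_disconnected_pairs_never_in_neighborhood(self):
        net = make_network([(0, 1)], 3)
        nbh = neighborhoods(net, percentile=99)
        assert 2 not in nbh.as_sets()[0]
        assert nbh.as_sets()[2] == {2}

    def test_single_node(self):
        net = make_network([], 1)
        nbh = neighborhoods(net)
        assert nbh.as_sets() == {0: {0}}


class TestSafeScores:
    def test_constant_attribute_all_zero_scores(self):
        net = make_network([(0, 1), (1, 2), (2, 3)], 4)
        nbh = neighborhoods(net)
        res = safe_scores(net, make_attr(net, [2.0] * 4), nbh, 199, seed=0)
        np.testing.assert_array_equal(res.scores, 0.0)
        np.testing.assert_array_equal(res.p_values, 1.0)

    def test_concentrated_mass_detected(self):
        # ring of 100 nodes; attribute 1 on five contiguous nodes
        edges = [(i, (i + 1) % 100) for i in range(100)]
        net = make_network(edges, 100)
        values = np.zeros(100)
        values[40:45] = 1.0
        nbh = neighborhoods(net, percentile=2.0)
        res = safe_scores(net, make_attr(net, values), nbh, 999, seed=1)
        assert res.scores[42] >= 0.9

    def test_p_floor_maps_to_score_one(self):
        # minimum attainable p = 1/(P+1) must give score exactly 1
        result = SAFEResult(
            variable="v",
            node_ids=[0],
            observed=np.array([1.0]),
            p_values=np.array([1.0 / 200.0]),
            scores=np.array([1.0]),
            n_permutations=199,
            neighborhood_threshold=1,
        )
        assert result.scores[0] == 1.0

    def test_scores_monotone_in_p(self):
        net = make_network([(i, i + 1) for i in range(9)], 10)
        rng = np.random.default_rng(0)
        nbh = neighborhoods(net, percentile=5)
        res = safe_scores(net, make_attr(net, rng.random(10)), nbh, 499, seed=2)
        order_p = np.argsort(res.p_values)
        order_s = np.argsort(-res.scores)
        # p ascending == score descending (ties aside): compare sorted pairs
        assert np.all(np.diff(res.scores[order_p]) <= 1e-12)
        assert np.all(np.diff(res.p_values[order_s]) >= -1e-12)

    def test_node_relabeling_permutes_scores(self):
        """Relabelling node ids permutes observed statistics exactly and
        p-values up to Monte-Carlo error of the permutation null."""
        edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
        net = make_network(edges, 5)
        values = np.array([0.1, 0.9, 0.2, 0.8, 0.3])
        nbh = neighborhoods(net, percentile=10)
        res = safe_scores(net, make_attr(net, values), nbh, 4999, seed=3)

        # relabel nodes by reversing ids: i -> 4 - i
        redges = [(4 - a, 4 - b) for a, b in edges]
        rnet = make_network(redges, 5)
        rnbh = neighborhoods(rnet, percentile=10)
        rres = safe_scores(rnet, make_attr(rnet, values[::-1]), rnbh, 4999, seed=3)
        np.testing.assert_allclose(rres.observed, res.observed[::-1], atol=1e-12)
        np.testing.assert_allclose(rres.p_values, res.p_values[::-1], atol=0.05)

    def test_deterministic_given_seed(self):
        net = path_network(6)
        nbh = neighborhoods(net)
        attr = node_values(net, {f"s{i}": float(i % 3) for i in range(8)}, "x")
        a = safe_scores(net, attr, nbh, 299, seed=9)
        b = safe_scores(net, attr, nbh, 299, seed=9)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_rare_dispersed_label_not_enriched(self):
        """A rare label spread uniformly across the network yields no
        significantly enriched nodes — the low-sample-size caveat."""
        edges = [(i, (i + 1) % 60) for i in range(60)]
        net = make_network(edges, 60)
        values = np.zeros(60)
        values[::12] = 0.2  # 5 occurrences, evenly spaced
        nbh = neighborhoods(net, percentile=2)
        res = safe_scores(net, make_attr(net, values), nbh, 999, seed=4)
        assert enriched_nodes(res, alpha=0.05) == set()


class TestEnrichedAndRanking:
    @staticmethod
    def _result(p_values, scores, name="v", P=999):
        n = len(p_values)
        return SAFEResult(
            variable=name,
            node_ids=list(range(n)),
            observed=np.zeros(n),
            p_values=np.asarray(p_values, float),
            scores=np.asarray(scores, float),
            n_permutations=P,
            neighborhood_threshold=1,
        )

    def test_all_p_one_empty(self):
        res = self._result([1.0, 1.0], [0.0, 0.0])
        assert enriched_nodes(res, 0.05) == set()

    def test_floor_p_included(self):
        res = self._result([1.0 / 5001.0], [1.0], P=5000)
        assert enriched_nodes(res, 0.05) == {0}

    def test_boundary_alpha_excluded(self):
        res = self._result([0.05, 0.049], [0.5, 0.5])
        assert enriched_nodes(res, 0.05) == {1}

    def test_enriched_score_is_sum_over_enriched(self):
        res = self._result([0.01, 0.2, 0.001], [0.6, 0.9, 0.8])
        assert safe_enriched_score(res, 0.05) == pytest.approx(0.6 + 0.8)
        assert safe_enriched_score(self._result([1.0], [0.0])) == 0.0

    def test_ranking_descending_with_lexicographic_ties(self):
        results = [
            self._result([0.001], [0.4], name="B"),
            self._result([0.001], [0.9], name="A"),
            self._result([0.001], [0.4], name="Ab"),
        ]
        ranking = rank_variables(results, 0.05)
        assert list(ranking["variable"]) == ["A", "Ab", "B"]


class TestTypeICalibration:
    def test_null_attribute_rejection_rate(self):
        """Attribute values drawn independently of topology: the fraction
        of nodes with p < 0.05 is ~0.05 averaged over many seeds."""
        edges = [(i, (i + 1) % 40) for i in range(40)] + [
            (i, (i + 2) % 40) for i in range(40)
        ]
        net = make_network(edges, 40)
        nbh = neighborhoods(net, percentile=2)
        rates = []
        rng = np.random.default_rng(0)
        for seed in range(50):
            values = rng.normal(size=40)
            res = safe_scores(net, make_attr(net, values), nbh, 999, seed=seed)
            rates.append(np.mean(res.p_values < 0.05))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)
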