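import itertools

import networkx as nx
import pytest

from interomix import (LandscapeParams, assign_modules, centrality_landscape,
                       summarize_modules)
from interomix.errors import ValidationError


def brute_force_centers(g, scores):
    """Oracle: a node is a centre iff no neighbour has a strictly greater
    (score, lexicographically-smaller-name) key."""
    centers = []
    for v in g:
        better = any(
            scores[nb] > scores[v] or (scores[nb] == scores[v] and str(nb) < str(v))
            for nb in g.adj[v]
        )
        if not better:
            centers.append(v)
    return sorted(centers)


class TestScores:
    def test_path_with_degree_weights(self, path_graph):
        scores = centrality_landscape(path_graph, LandscapeParams(radius=1))
        assert scores == {"a": 4.0, "b": 6.0, "c": 4.0}

    def test_isolated_node_scores_self_term_only(self):
        g = nx.Graph()
        g.add_node("x")
        for r in (1, 2, 5):
            scores = centrality_landscape(g, LandscapeParams(radius=r, weights="unit"))
            assert scores["x"] == r + 1

    def test_vertex_transitive_graph_has_equal_scores(self):
        g = nx.cycle_graph(7)
        scores = centrality_landscape(g, LandscapeParams(radius=2))
        assert len(set(scores.values())) == 1

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            LandscapeParams(radius=0)
        with pytest.raises(ValidationError):
            LandscapeParams(weights="betweenness")


class TestAssignment:
    def test_path_single_center(self, path_graph):
        scores = centrality_landscape(path_graph, LandscapeParams(radius=1))
        assignment = assign_modules(path_graph, scores)
        assert assignment.centers == ("b",)
        assert set(assignment.membership.values()) == {"b"}

    def test_triangle_tie_break_to_smallest_name(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        scores = centrality_landscape(g, LandscapeParams(radius=1))
        assert len(set(scores.values())) == 1
        assignment = assign_modules(g, scores)
        assert assignment.centers == ("a",)
        assert assignment.target["b"] == "a" and assignment.target["c"] == "a"

    def test_edgeless_graph_all_singletons(self):
        g = nx.empty_graph(3)
        scores = centrality_landscape(g, LandscapeParams())
        assignment = assign_modules(g, scores)
        assert len(assignment.centers) == 3
        assert all(assignment.membership[v] == v for v in g)

    def test_deterministic_across_runs(self, small_sim):
        g = small_sim.db.graph.subgraph(sorted(small_sim.truth.module_genes))
        params = LandscapeParams(radius=2)
        first = assign_modules(g, centrality_landscape(g, params))
        second = assign_modules(g, centrality_landscape(g, params))
        assert first.centers == second.centers
        assert first.membership == second.membership

    def test_ascent_chains_terminate_at_their_center(self):
        g = nx.random_geometric_graph(40, 0.3, seed=2)
        scores = centrality_landscape(g, LandscapeParams())
        assignment = assign_modules(g, scores)
        for v in g:
            cur, steps = v, 0
            while assignment.target[cur] != cur:
                cur = assignment.target[cur]
                steps += 1
                assert steps <= g.number_of_nodes()
            assert assignment.membership[v] == cur


def _all_graphs(n):
    pairs = list(itertools.combinations(range(n), 2))
    for mask in range(2 ** len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(p for i, p in enumerate(pairs) if mask >> i & 1)
        yield g


@pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
def test_centers_match_local_maxima_oracle_exhaustively(n):
    """Every labelled graph on <= 5 nodes: centres = brute-force local maxima."""
    params = LandscapeParams(radius=1)
    for g in _all_graphs(n):
        scores = centrality_landscape(g, params)
        assignment = assign_modules(g, scores)
        assert list(assignment.centers) == brute_force_centers(g, scores)


@pytest.mark.parametrize("seed", range(100))
def test_centers_match_oracle_on_random_graphs(seed):
    rng = nx.utils.create_random_state(seed)
    g = nx.gnp_random_graph(rng.randint(6, 8), rng.uniform(0.2, 0.7), seed=rng)
    for params in (LandscapeParams(radius=1), LandscapeParams(radius=2, weights="unit")):
        scores = centrality_landscape(g, params)
        assignment = assign_modules(g, scores)
        assert list(assignment.centers) == brute_force_centers(g, scores)


class TestBarbell:
    def test_two_cliques_with_bridge_path_give_one_center_each(self):
        # two K5 joined through a single intermediate bridge node: the clique
        # attachment nodes are the two local maxima (r=1, degree weights)
        g = nx.barbell_graph(5, 1)
        scores = centrality_landscape(g, LandscapeParams(radius=1))
        assignment = assign_modules(g, scores)
        assert len(assignment.centers) == 2
        assert assignment.membership[0] in range(5)
        assert assignment.membership[10] in range(6, 11)

    def test_directly_bridged_cliques_merge_into_one_center(self):
        # with the bridge endpoints adjacent their scores tie, and the
        # lexicographic tie-break absorbs one maximum into the other
        g = nx.barbell_graph(5, 0)
        scores = centrality_landscape(g, LandscapeParams(radius=1))
        assignment = assign_modules(g, scores)
        assert len(assignment.centers) == 1


def test_summarize_path_module(path_graph):
    scores = centrality_landscape(path_graph, LandscapeParams(radius=1))
    table = summarize_modules(assign_modules(path_graph, scores))
    assert len(table) == 1
    row = table.iloc[0]
    assert (row["center"], row["size"]) == ("b", 3)
    assert row["mean_score"] == pytest.approx(14 / 3)


def test_summarize_sizes_sum_to_node_count(small_sim):
    g = small_sim.db.graph.subgraph(sorted(small_sim.truth.module_genes))
    assignment = assign_modules(g, centrality_landscape(g, LandscapeParams()))
    table = summarize_modules(assignment)
    assert table["size"].sum() == g.number_of_nodes()


def test_summarize_empty():
    g = nx.Graph()
    assignment = assign_modules(g, {})
    assert summarize_modules(assignment).empty
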