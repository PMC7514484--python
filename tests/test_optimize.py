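"""Spanning-forest pruning, hub detection, and edge re-insertion."""

import networkx as nx
import numpy as np
import pytest

from engnet import (
    ThresholdConfig,
    detect_hubs,
    engnet,
    generate_fixture,
    maximum_spanning_forest,
    readd_hub_edges,
)

from oracles import max_spanning_forest_weight


def total_weight(g: nx.Graph) -> float:
    return sum(d["weight"] for _, _, d in g.edges(data=True))


def test_known_square_graph(weighted_square):
    forest = maximum_spanning_forest(weighted_square)
    assert set(map(tuple, map(sorted, forest.edges()))) == {
        ("A", "B"), ("B", "C"), ("C", "D")
    }
    assert total_weight(forest) == pytest.approx(2.4)


def test_tree_input_returned_unchanged():
    tree = nx.Graph()
    tree.add_weighted_edges_from([("a", "b", 0.3), ("b", "c", 0.9), ("c", "d", 0.1)])
    forest = maximum_spanning_forest(tree)
    assert set(forest.edges()) == set(tree.edges())


def test_disconnected_triangles_pruned_per_component():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)])
    g.add_weighted_edges_from([("x", "y", 0.6), ("y", "z", 0.5), ("x", "z", 0.4)])
    forest = maximum_spanning_forest(g)
    assert set(map(tuple, map(sorted, forest.edges()))) == {
        ("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")
    }


def test_forest_matches_enumeration_oracle_on_random_graphs():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        n = rng.integers(2, 8)
        p = rng.uniform(0.3, 0.9)
        g = nx.gnp_random_graph(int(n), float(p), seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform())
        forest = maximum_spanning_forest(g)
        assert nx.is_forest(forest)
        assert set(forest.nodes) == set(g.nodes)
        for component in nx.connected_components(g):
            assert nx.is_connected(forest.subgraph(component))
        assert total_weight(forest) == pytest.approx(max_spanning_forest_weight(g))


def test_forest_idempotent(weighted_square):
    once = maximum_spanning_forest(weighted_square)
    twice = maximum_spanning_forest(once)
    assert set(once.edges()) == set(twice.edges())


def test_tie_break_is_lexicographic():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 0.5), ("a", "c", 0.5), ("b", "c", 0.5)])
    forest = maximum_spanning_forest(g)
    assert set(map(tuple, map(sorted, forest.edges()))) == {("a", "b"), ("a", "c")}


def test_empty_network_gives_empty_forest():
    forest = maximum_spanning_forest(nx.Graph())
    assert forest.number_of_nodes() == 0


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def test_star_center_is_the_only_hub():
    star = nx.star_graph(4)  # degrees 4,1,1,1,1; mean 1.6
    assert detect_hubs(star) == {0}


def test_regular_cycle_has_no_hubs():
    assert detect_hubs(nx.cycle_graph(5)) == frozenset()


def test_path_interior_nodes_are_hubs():
    path = nx.path_graph(["A", "B", "C", "D"])  # degrees 1,2,2,1; mean 1.5
    assert detect_hubs(path) == {"B", "C"}


def test_empty_network_has_no_hubs():
    assert detect_hubs(nx.Graph()) == frozenset()


# ---------------------------------------------------------------------------
# re-insertion
# ---------------------------------------------------------------------------

def _ensemble_and_pruned():
    ensemble = nx.Graph()
    ensemble.add_weighted_edges_from([
        ("h", "a", 0.9), ("h", "b", 0.85), ("h", "c", 0.8),
        ("a", "b", 0.85), ("b", "c", 0.99), ("h", "d", 0.7), ("d", "e", 0.95),
    ])
    pruned = maximum_spanning_forest(ensemble)
    return ensemble, pruned


def test_strictly_exceeding_hub_edge_readded():
    ensemble, pruned = _ensemble_and_pruned()
    hubs = frozenset({"h"})
    final = readd_hub_edges(ensemble, pruned, hubs, th_beta=0.8)
    removed_hub_edges = [
        e for e in ensemble.edges() if not pruned.has_edge(*e)
        and ("h" in e)
    ]
    for u, v in removed_hub_edges:
        expected = ensemble[u][v]["weight"] > 0.8
        assert final.has_edge(u, v) == (pruned.has_edge(u, v) or expected)


def test_boundary_weight_not_readded_strict():
    ensemble = nx.Graph()
    ensemble.add_weighted_edges_from([("h", "a", 0.9), ("h", "b", 0.85), ("a", "b", 0.8)])
    pruned = maximum_spanning_forest(ensemble)
    assert not pruned.has_edge("a", "b")
    final = readd_hub_edges(ensemble, pruned, frozenset({"a"}), th_beta=0.8)
    assert not final.has_edge("a", "b")  # 0.8 does not exceed 0.8
    inclusive = readd_hub_edges(ensemble, pruned, frozenset({"a"}), th_beta=0.8,
                                inclusive=True)
    assert inclusive.has_edge("a", "b")


def test_non_hub_edge_never_readded():
    ensemble = nx.Graph()
    ensemble.add_weighted_edges_from(
        [("x", "y", 0.99), ("x", "z", 0.995), ("y", "z", 0.999)]
    )
    pruned = maximum_spanning_forest(ensemble)
    final = readd_hub_edges(ensemble, pruned, frozenset(), th_beta=0.5)
    assert set(final.edges()) == set(pruned.edges())


def test_readded_weights_come_from_ensemble():
    ensemble, pruned = _ensemble_and_pruned()
    final = readd_hub_edges(ensemble, pruned, frozenset({"h"}), th_beta=0.0)
    for u, v, d in final.edges(data=True):
        assert d["weight"] == ensemble[u][v]["weight"]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_pipeline_nesting_invariants(two_module_matrix, default_thresholds):
    result = engnet(two_module_matrix, default_thresholds)
    ensemble_edges = set(map(tuple, map(sorted, result.ensemble.edges())))
    pruned_edges = set(map(tuple, map(sorted, result.pruned.edges())))
    final_edges = set(map(tuple, map(sorted, result.final.edges())))
    assert pruned_edges <= final_edges <= ensemble_edges
    assert set(result.removed_edges) == ensemble_edges - pruned_edges
    # |pruned| = n - c exactly
    n = result.pruned.number_of_nodes()
    c = nx.number_connected_components(result.pruned)
    assert result.pruned.number_of_edges() == n - c
    assert nx.is_forest(result.pruned)
    # every re-added edge is hub-incident with w_en > th_beta
    for u, v in final_edges - pruned_edges:
        assert u in result.hub_nodes or v in result.hub_nodes
        assert result.ensemble[u][v]["weight"] > default_thresholds.th_beta


def test_pipeline_deterministic(two_module_matrix, default_thresholds):
    a = engnet(two_module_matrix, default_thresholds)
    b = engnet(two_module_matrix, default_thresholds)
    assert sorted(a.final.edges(data="weight")) == sorted(b.final.edges(data="weight"))
    assert a.hub_nodes == b.hub_nodes


def test_independent_noise_genes_give_near_empty_network():
    matrix = generate_fixture(20, 200, [], seed=13)
    thresholds = ThresholdConfig(0.9, 0.9, 0.9, 0.9)
    result = engnet(matrix, thresholds)
    assert result.ensemble.number_of_edges() <= 1


def test_disjoint_modules_yield_separate_components(two_module_matrix,
                                                    default_thresholds):
    result = engnet(two_module_matrix, default_thresholds)
    components = list(nx.connected_components(result.final))
    assert len(components) >= 2
    for comp in components:
        prefixes = {g.split("_")[0] for g in comp}
        assert len(prefixes) == 1  # no edge joins the two planted modules
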