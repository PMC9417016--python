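"""Social-map aggregation, display filters, group maps, focal subgraphs."""

import numpy as np
import pandas as pd
import pytest
from conftest import random_component_map

from repmap import (
    CognitiveMap,
    MapCollection,
    ValidationError,
    build_social_map,
    filter_social_map,
    focus_subgraph,
    group_social_maps,
)


def _cmap(rid, nodes, edges):
    return CognitiveMap(respondent_id=rid, nodes=set(nodes), edges=dict(edges), level="component")


# -- aggregation -------------------------------------------------------------


def test_build_social_map_tallies():
    maps = [_cmap("r1", {"a", "b"}, {("a", "b"): 1}), _cmap("r2", {"a", "b"}, {("a", "b"): 1})]
    scm = build_social_map(maps)
    assert scm.edge_counts[("a", "b")] == (2, 0)
    assert scm.weight_sum(("a", "b")) == 2
    assert scm.occurrence(("a", "b")) == 2
    assert scm.node_citations == {"a": 2, "b": 2}


def test_cancellation_retained_in_tallies():
    maps = [_cmap("r1", {"a", "b"}, {("a", "b"): 1}), _cmap("r2", {"a", "b"}, {("a", "b"): -1})]
    scm = build_social_map(maps)
    assert scm.weight_sum(("a", "b")) == 0
    assert scm.occurrence(("a", "b")) == 2
    assert scm.edge_counts[("a", "b")] == (1, 1)


def test_empty_collection_errors():
    with pytest.raises(ValidationError, match="no maps"):
        build_social_map([])


def test_weight_matrix_equals_padded_sum_oracle(sim_world):
    """SCM weight matrix == entrywise sum of padded individual matrices."""
    collection, _ = sim_world
    scm = build_social_map(collection)
    order = sorted(scm.node_citations)
    expected = np.zeros((len(order), len(order)))
    for m in collection.maps:
        expected += m.adjacency_frame(order).to_numpy()
    np.testing.assert_array_equal(scm.weight_matrix(order).to_numpy(), expected)


def test_aggregation_permutation_invariant(tiny_maps):
    a = build_social_map(tiny_maps)
    b = build_social_map(list(reversed(tiny_maps)))
    assert a.node_citations == b.node_citations
    assert a.edge_counts == b.edge_counts


def test_conservation_links_equal_occurrence_sum(sim_world):
    collection, _ = sim_world
    scm = build_social_map(collection)
    total_links = sum(m.n_links for m in collection.maps)
    assert sum(scm.occurrence(p) for p in scm.edge_counts) == total_links


# -- filters -----------------------------------------------------------------


def test_filter_strict_node_threshold():
    # node cited by 3/32 is removed at >10% (3/32 ~ 0.094)
    maps = [_cmap(f"r{i}", {"common"}, {}) for i in range(32)]
    for i in range(3):
        maps[i].nodes.add("rare")
    scm = build_social_map(maps)
    filtered = filter_social_map(scm, node_freq_min=0.10)
    assert "rare" not in filtered.node_citations
    assert "common" in filtered.node_citations


def test_filter_strict_edge_threshold_boundaries():
    maps = []
    for i in range(11):
        maps.append(_cmap(f"a{i}", {"x", "y"}, {("x", "y"): 1}))
    for i in range(10):
        maps.append(_cmap(f"b{i}", {"u", "v"}, {("u", "v"): 1}))
    scm = build_social_map(maps)
    filtered = filter_social_map(scm, edge_occ_min=10)
    assert ("x", "y") in filtered.edge_counts  # occurrence 11 > 10: kept
    assert ("u", "v") not in filtered.edge_counts  # occurrence 10: excluded


def test_filter_zero_thresholds_identity(sim_world):
    collection, _ = sim_world
    scm = build_social_map(collection)
    same = filter_social_map(scm, 0, 0)
    assert same.node_citations == scm.node_citations
    assert same.edge_counts == scm.edge_counts


def test_filter_monotone_in_thresholds(sim_world):
    collection, _ = sim_world
    scm = build_social_map(collection)
    prev_nodes, prev_edges = scm.n_nodes, scm.n_edges
    for freq, occ in [(0.1, 2), (0.3, 5), (0.5, 10)]:
        f = filter_social_map(scm, freq, occ)
        assert f.n_nodes <= prev_nodes and f.n_edges <= prev_edges
        prev_nodes, prev_edges = f.n_nodes, f.n_edges


# -- group maps --------------------------------------------------------------


def test_group_maps_single_group_equals_full(tiny_collection):
    full = build_social_map(tiny_collection)
    groups = group_social_maps(tiny_collection, dict.fromkeys(tiny_collection.respondent_ids, "all"))
    single = groups["all"]
    assert single.node_citations == full.node_citations
    assert single.edge_counts == full.edge_counts


def test_group_maps_weight_matrices_sum_to_full(sim_world):
    collection, truth = sim_world
    full = build_social_map(collection)
    groups = group_social_maps(collection, truth.respondent_cluster)
    order = sorted(full.node_citations)
    summed = sum(g.weight_matrix(order).to_numpy() for g in groups.values())
    np.testing.assert_array_equal(summed, full.weight_matrix(order).to_numpy())


def test_group_maps_singleton_and_unlabeled(tiny_collection):
    labels = {"r1": "solo", "r2": "rest", "r3": "rest"}
    groups = group_social_maps(tiny_collection, labels)
    solo = groups["solo"]
    m1 = tiny_collection.maps[0]
    assert solo.R == 1
    assert set(solo.node_citations) == m1.nodes
    assert all(v == 1 for v in solo.node_citations.values())
    with pytest.raises(ValidationError, match="unlabeled"):
        group_social_maps(tiny_collection, {"r1": "x"})


# -- focal subgraphs ---------------------------------------------------------


def test_focus_one_hop_neighborhood():
    maps = [_cmap("r1", {"a", "fires", "b", "c"}, {("a", "fires"): 1, ("fires", "b"): -1})]
    scm = build_social_map(maps)
    sub = focus_subgraph(scm, ["fires"], edge_occ_min=0)
    assert set(sub.node_citations) == {"a", "fires", "b"}  # c not adjacent
    assert set(sub.edge_counts) == {("a", "fires"), ("fires", "b")}


def test_focus_strict_occurrence_boundary():
    maps = [_cmap(f"r{i}", {"fires", "x"}, {("fires", "x"): 1}) for i in range(2)]
    scm = build_social_map(maps)
    sub = focus_subgraph(scm, ["fires"], edge_occ_min=2)
    assert sub.edge_counts == {}  # occurrence 2 excluded at >2
    assert set(sub.node_citations) == {"fires"}  # focal node retained


def test_focus_whole_node_set_identity(sim_world):
    collection, _ = sim_world
    scm = build_social_map(collection)
    sub = focus_subgraph(scm, sorted(scm.node_citations), edge_occ_min=0)
    assert sub.edge_counts == scm.edge_counts
    assert set(sub.node_citations) == set(scm.node_citations)


def test_focus_type_expansion_and_absent(catalog, tiny_collection):
    scm = build_social_map(tiny_collection)
    sub = focus_subgraph(scm, ["threats"], edge_occ_min=0, catalog=catalog)
    assert "fires" in sub.node_citations and "hunting" in sub.node_citations
    with pytest.raises(ValidationError, match="absent"):
        focus_subgraph(scm, ["no_such_node"], catalog=catalog)
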