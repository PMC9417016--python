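"""Domain types, file round-trips, catalog invariants, collection validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repmap import (
    CognitiveMap,
    CondensationCatalog,
    MapCollection,
    ValidationError,
    normalize_label,
    validate_collection,
)
from repmap.io import (
    read_adjacency_matrix,
    read_catalog,
    read_edge_list,
    write_adjacency_matrix,
    write_catalog,
    write_edge_list,
)


# -- label normalization and catalog invariants -----------------------------


def test_normalize_label_trims_collapses_casefolds():
    assert normalize_label("  Zebu   raising ") == "zebu raising"


def test_catalog_normalized_matching(catalog):
    # verbatim spellings with stray whitespace/case resolve to the component
    assert catalog.map_label("  zebu RAISING ", "raw", "component") == "zebu_raising"
    assert catalog.map_label("woods", "raw", "type") == "habitats"
    assert catalog.category_of("fires", "component") == "negative_human_action"


@pytest.mark.parametrize(
    "rows, message",
    [
        ([("a", "x", "t1", "social"), ("b", "x", "t2", "social")], "two types"),
        ([("a", "x", "t1", "social"), ("b", "y", "t1", "biophysical")], "two categories"),
        ([("a", "x", "t1", "wrong_category")], "unknown category"),
        ([("a", "x", "t1", "social"), (" A ", "x", "t1", "social")], "duplicate raw label"),
    ],
)
def test_catalog_invariant_breaches_raise(rows, message):
    with pytest.raises(ValidationError, match=message):
        CondensationCatalog(rows)


def test_catalog_cannot_refine(catalog):
    with pytest.raises(ValidationError, match="finer"):
        catalog.map_label("habitats", "type", "component")


def test_catalog_roundtrip_and_study_scale_fixture(tmp_path, sim_world):
    # the generated universe mirrors the study's scale: 162/32/6
    collection, _ = sim_world
    path = tmp_path / "catalog.csv"
    write_catalog(collection.catalog, path)
    loaded = read_catalog(path)
    assert loaded.n_components == 162
    assert loaded.n_types == 32
    assert len(loaded.categories_used) == 6
    assert loaded.entries == collection.catalog.entries


# -- cognitive map invariants -----------------------------------------------


def test_map_rejects_self_loop_and_bad_sign():
    with pytest.raises(ValidationError, match="self-loop"):
        CognitiveMap(respondent_id="r", nodes={"a"}, edges={("a", "a"): 1})
    with pytest.raises(ValidationError, match="sign"):
        CognitiveMap(respondent_id="r", nodes={"a", "b"}, edges={("a", "b"): 2})
    with pytest.raises(ValidationError, match="endpoint"):
        CognitiveMap(respondent_id="r", nodes={"a"}, edges={("a", "b"): 1})


# -- adjacency matrix I/O ----------------------------------------------------


def test_read_adjacency_single_edge(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(",A,B\nA,0,1\nB,0,0\n")
    m = read_adjacency_matrix(path, "r1")
    assert m.nodes == {"A", "B"}
    assert m.edges == {("A", "B"): 1}
    assert m.level == "raw"


def test_read_adjacency_all_zero_keeps_isolated_nodes(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(",A,B,C\nA,0,0,0\nB,0,0,0\nC,0,0,0\n")
    m = read_adjacency_matrix(path, "r1")
    assert m.nodes == {"A", "B", "C"}
    assert m.n_links == 0


def test_read_adjacency_error_cases(tmp_path):
    loop = tmp_path / "loop.csv"
    loop.write_text(",A,B\nA,1,0\nB,0,0\n")
    with pytest.raises(ValidationError, match="self-loop"):
        read_adjacency_matrix(loop, "r1")
    with pytest.warns(UserWarning):
        m = read_adjacency_matrix(loop, "r1", drop_self_loops=True)
    assert m.n_links == 0

    weights = tmp_path / "w.csv"
    weights.write_text(",A,B\nA,0,0.5\nB,0,0\n")
    with pytest.raises(ValidationError, match="outside"):
        read_adjacency_matrix(weights, "r1")
    with pytest.warns(UserWarning):
        m = read_adjacency_matrix(weights, "r1", coerce_sign=True)
    assert m.edges == {("A", "B"): 1}

    rect = tmp_path / "rect.csv"
    rect.write_text(",A,B\nA,0,1\n")
    with pytest.raises(ValidationError, match="square"):
        read_adjacency_matrix(rect, "r1")

    dup = tmp_path / "dup.csv"
    dup.write_text(",A, a\nA,0,1\n a,0,0\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_adjacency_matrix(dup, "r1")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_adjacency_roundtrip_random_maps(tmp_path_factory, seed):
    """read(write(m)) reproduces nodes and edges exactly on random +/-1 maps."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 11))
    nodes = [f"n{i}" for i in range(n)]
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    k = int(rng.integers(0, len(pairs) + 1))
    chosen = rng.choice(len(pairs), size=k, replace=False)
    edges = {pairs[i]: int(rng.choice([1, -1])) for i in chosen}
    m = CognitiveMap(respondent_id="r", nodes=set(nodes), edges=edges)
    path = tmp_path_factory.mktemp("rt") / "m.csv"
    write_adjacency_matrix(m, path)
    back = read_adjacency_matrix(path, "r")
    assert back.nodes == m.nodes
    assert back.edges == m.edges


# -- edge list I/O -----------------------------------------------------------


def test_edge_list_basic_and_multi_respondent(tmp_path):
    path = tmp_path / "e.csv"
    path.write_text(
        "respondent_id,source,target,sign\n"
        "r1,A,B,1\nr1,B,C,-1\n"
        "r2,A,,\n"
        "r3,X,Y,1\n"
    )
    maps = read_edge_list(path)
    assert len(maps) == 3
    m1 = maps[0]
    assert m1.nodes == {"A", "B", "C"} and m1.n_links == 2
    assert maps[1].nodes == {"A"} and maps[1].n_links == 0  # isolated node row


def test_edge_list_conflicting_duplicate_names_pair(tmp_path):
    path = tmp_path / "e.csv"
    path.write_text("respondent_id,source,target,sign\nr1,A,B,1\nr1,A,B,-1\n")
    with pytest.raises(ValidationError, match=r"'A'.*'B'"):
        read_edge_list(path)


def test_edge_list_roundtrip(tmp_path, tiny_maps):
    path = tmp_path / "e.csv"
    write_edge_list(tiny_maps, path)
    back = read_edge_list(path, level="component")
    assert [m.respondent_id for m in back] == [m.respondent_id for m in tiny_maps]
    for a, b in zip(back, tiny_maps):
        assert a.nodes == b.nodes and a.edges == b.edges


# -- collection validation ---------------------------------------------------


def test_validate_collection_clean(tiny_collection):
    report = validate_collection(tiny_collection)
    assert report.valid
    assert report.to_frame().empty


def test_validate_collection_reports_unresolvable_and_duplicates(catalog, tiny_maps):
    bad = CognitiveMap(
        respondent_id="r1",  # duplicate id
        nodes={"forest", "not_in_catalog"},
        edges={},
        level="component",
    )
    report = validate_collection(MapCollection(maps=tiny_maps + [bad], catalog=catalog))
    kinds = {i.kind for i in report.issues}
    assert not report.valid
    assert "duplicate_respondent" in kinds
    details = [i.detail for i in report.issues if i.kind == "unresolvable_label"]
    assert any("not_in_catalog" in d for d in details)
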