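"""Shared fixtures: hand-built catalogs/maps and a seeded synthetic world."""

import numpy as np
import pytest

from repmap import (
    CognitiveMap,
    CondensationCatalog,
    GeneratorConfig,
    MapCollection,
    generate_collection,
)

CATALOG_ROWS = [
    # raw_label, component, type, category
    ("forest", "forest", "habitats", "biophysical"),
    ("woods", "forest", "habitats", "biophysical"),
    ("rivers", "rivers", "habitats", "biophysical"),
    ("lemur", "lemurs", "fauna", "biophysical"),
    ("sifaka", "lemurs", "fauna", "biophysical"),
    ("local people", "local_people", "people", "social"),
    ("villagers", "local_people", "people", "social"),
    ("zebu thieves", "zebu_thieves", "people", "social"),
    (" Zebu raising ", "zebu_raising", "agriculture_husbandry", "social"),
    ("water supply", "water_supply", "provisioning", "ecosystem_service"),
    ("hunting", "hunting", "threats", "negative_human_action"),
    ("fire", "fires", "threats", "negative_human_action"),
    ("burning", "fires", "threats", "negative_human_action"),
    ("ecotourism", "ecotourism", "conservation", "positive_human_action"),
    ("erosion", "erosion", "degradation", "ecosystem_disservice"),
]


@pytest.fixture(scope="session")
def catalog():
    return CondensationCatalog(CATALOG_ROWS)


@pytest.fixture
def tiny_maps():
    """Three small component-level maps over the shared catalog."""
    m1 = CognitiveMap(
        respondent_id="r1",
        nodes={"forest", "lemurs", "fires", "local_people"},
        edges={("fires", "forest"): -1, ("forest", "lemurs"): 1, ("local_people", "fires"): 1},
        respondent_group="researcher",
        level="component",
    )
    m2 = CognitiveMap(
        respondent_id="r2",
        nodes={"forest", "fires", "hunting", "lemurs"},
        edges={("fires", "forest"): -1, ("hunting", "lemurs"): -1},
        respondent_group="ngo_member",
        level="component",
    )
    m3 = CognitiveMap(
        respondent_id="r3",
        nodes={"forest", "rivers", "water_supply"},
        edges={("rivers", "water_supply"): 1, ("forest", "rivers"): 1},
        respondent_group="tour_operator",
        level="component",
    )
    return [m1, m2, m3]


@pytest.fixture
def tiny_collection(tiny_maps, catalog):
    return MapCollection(maps=tiny_maps, catalog=catalog)


@pytest.fixture(scope="session")
def sim_world():
    """The default paper-calibrated synthetic world at seed 42."""
    return generate_collection(GeneratorConfig(seed=42))


def random_component_map(rng, respondent_id, universe, max_edges=None, level="component"):
    """Small random signed map over a given universe of node ids."""
    universe = list(universe)
    n = rng.integers(2, len(universe) + 1)
    nodes = list(rng.choice(universe, size=n, replace=False))
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    n_edges = int(rng.integers(0, min(len(pairs), max_edges or len(pairs)) + 1))
    idx = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []
    edges = {pairs[i]: int(rng.choice([1, -1])) for i in np.atleast_1d(idx)}
    return CognitiveMap(
        respondent_id=str(respondent_id), nodes=set(nodes), edges=edges, level=level
    )
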