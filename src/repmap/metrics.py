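"""Per-map network metrics, node centrality, and the sampling saturation curve.

The nine *active* metrics per map — component count, link count, density,
and the six category proportions — are the variables later fed to the PCA
and clustering.  Centrality follows the fuzzy-cognitive-map convention:
degree centrality on absolute weights, which for signed unit edges is
simply in-degree + out-degree.  Density is the directed, no-self-loop
formula L / (N (N - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import (
    CATEGORIES,
    CognitiveMap,
    CondensationCatalog,
    MapCollection,
    ValidationError,
)

#: Category -> metrics-table column name.
PROP_COLUMNS = {
    "biophysical": "prop_biophysical",
    "social": "prop_social",
    "ecosystem_service": "prop_ecosystem_service",
    "ecosystem_disservice": "prop_ecosystem_disservice",
    "positive_human_action": "prop_positive_action",
    "negative_human_action": "prop_negative_action",
}

#: The nine active metric columns, in fixed documented order.
METRIC_COLUMNS = (
    "n_components",
    "n_links",
    "density",
    "prop_biophysical",
    "prop_social",
    "prop_ecosystem_service",
    "prop_ecosystem_disservice",
    "prop_positive_action",
    "prop_negative_action",
)


@dataclass(frozen=True)
class MapMetrics:
    n_components: int
    n_links: int
    density: float
    prop_biophysical: float
    prop_social: float
    prop_ecosystem_service: float
    prop_ecosystem_disservice: float
    prop_positive_action: float
    prop_negative_action: float

    def as_dict(self) -> dict:
        return {col: getattr(self, col) for col in METRIC_COLUMNS}


def density(n_nodes: int, n_links: int) -> float:
    """Directed density without self-loops: L / (N (N - 1)); 0 for N < 2."""
    if n_nodes < 2:
        return 0.0
    return n_links / (n_nodes * (n_nodes - 1))


def map_metrics(cmap: CognitiveMap, catalog: CondensationCatalog) -> MapMetrics:
    """The nine active metrics for one map.

    Isolated nodes count toward ``n_components`` and the category
    proportions: citing a component is the datum, linked or not.  Conflict
    edges are excluded from ``n_links``.
    """
    n = cmap.n_nodes
    counts = dict.fromkeys(CATEGORIES, 0)
    for node in cmap.nodes:
        try:
            cat = catalog.category_of(node, cmap.level)
        except ValidationError as exc:
            raise ValidationError(
                f"map {cmap.respondent_id!r}: node {node!r} has no category"
            ) from exc
        counts[cat] += 1
    props = {
        PROP_COLUMNS[cat]: (counts[cat] / n if n else 0.0) for cat in CATEGORIES
    }
    return MapMetrics(
        n_components=n,
        n_links=cmap.n_links,
        density=density(n, cmap.n_links),
        **props,
    )


def node_centrality(cmap: CognitiveMap) -> pd.DataFrame:
    """Degree centrality, within-map rank, and relative rank per node.

    centrality(v) = sum of |sign| over edges incident to v (in + out
    degree for unit signed edges); isolated nodes score 0.  Rank 1 is the
    most central node; ties receive average ranks to avoid order-of-input
    artifacts.  Relative rank is rank / n_nodes.
    """
    nodes = sorted(cmap.nodes)
    scores = dict.fromkeys(nodes, 0)
    for (src, tgt) in cmap.edges:
        scores[src] += 1
        scores[tgt] += 1
    values = np.array([scores[n] for n in nodes], dtype=float)
    ranks = rankdata(-values, method="average") if nodes else np.array([])
    return pd.DataFrame(
        {
            "centrality": values,
            "rank": ranks,
            "relative_rank": ranks / len(nodes) if nodes else ranks,
        },
        index=pd.Index(nodes, name="node"),
    )


def metrics_table(collection: MapCollection) -> pd.DataFrame:
    """One row per respondent: the nine active metrics plus the group column."""
    if collection.catalog is None:
        raise ValidationError("metrics table requires a catalog for categories")
    collection.level  # raises on mixed levels
    rows = []
    for m in collection.maps:
        row = {"respondent_id": m.respondent_id}
        row.update(map_metrics(m, collection.catalog).as_dict())
        row["respondent_group"] = m.respondent_group
        rows.append(row)
    return pd.DataFrame(rows).set_index("respondent_id")[
        list(METRIC_COLUMNS) + ["respondent_group"]
    ]


def accumulation_curve(
    collection: MapCollection, n_permutations: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Component accumulation (saturation) curve over respondent orderings.

    For each k in 1..R, the mean (and SD) over random permutations of the
    number of unique components cited by the first k respondents.  The
    curve is monotone per permutation, and its endpoint is the total number
    of unique components regardless of ordering.
    """
    if collection.R == 0:
        raise ValidationError("accumulation curve of an empty collection")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    node_sets = [frozenset(m.nodes) for m in collection.maps]
    R = len(node_sets)
    rng = np.random.default_rng(seed)
    counts = np.empty((n_permutations, R))
    for p in range(n_permutations):
        order = rng.permutation(R)
        seen: set = set()
        for k, i in enumerate(order):
            seen |= node_sets[i]
            counts[p, k] = len(seen)
    return pd.DataFrame(
        {
            "k": np.arange(1, R + 1),
            "mean_unique": counts.mean(axis=0),
            "sd_unique": counts.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(R),
        }
    )
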